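import os

import numpy as np
import pytest

from firepriority import (
    PipelineConfig,
    SyntheticScenario,
    run,
    write_scenario,
)
from firepriority.grid import GridSpec, Raster


@pytest.fixture
def grid500() -> GridSpec:
    """Small 500 m analysis grid in a projected CRS."""
    return GridSpec("EPSG:2100", 300000.0, 4500000.0, 500.0, 500.0, 10, 10)


@pytest.fixture
def grid30() -> GridSpec:
    """30 m grid nested in grid500's top-left 3 km x 3 km."""
    return GridSpec("EPSG:2100", 300000.0, 4500000.0, 30.0, 30.0, 100, 100)


def mask_raster(grid: GridSpec, values) -> Raster:
    return Raster(grid, np.asarray(values, dtype=np.uint8), nodata=255)


@pytest.fixture(scope="session")
def scenario() -> SyntheticScenario:
    return SyntheticScenario(seed=12345)


@pytest.fixture(scope="session")
def scenario_dir(scenario, tmp_path_factory):
    d = tmp_path_factory.mktemp("scenario")
    manifest = write_scenario(scenario, d)
    return manifest


@pytest.fixture(scope="session")
def pipeline_run(scenario_dir, tmp_path_factory):
    """One full pipeline run on the session scenario, reused across tests."""
    out = tmp_path_factory.mktemp("out")
    cfg = PipelineConfig(
        burn_dir=scenario_dir["burn_dir"],
        dem_path=scenario_dir["dem"],
        protected_path=scenario_dir["protected"],
        regions_path=scenario_dir["regions"],
        land_path=scenario_dir["land"],
        out_dir=os.fspath(out),
    )
    result = run(cfg)
    return cfg, result
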