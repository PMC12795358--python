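"""End-to-end orchestration: config, validation, the full pipeline run.

``run`` chains the four analysis stages — fire history, terrain,
protected areas, prioritization — on either a scenario directory written
by the synthetic generator or equivalently organized real inputs, and
writes every artifact the stages define (frequency/criterion/priority
GeoTIFFs, the regional CSV, an area-by-frequency CSV, and a JSON run log
with the config echo, input checksums and the per-stage pixel/km² chain).

All thresholds live in :class:`PipelineConfig` with the defaults of the
Greek national analysis: burns in two or more years of 2001–2023, slope
strictly above 15°, protection by any designation, all on a 500 m
analysis grid.
"""

from __future__ import annotations

import glob
import hashlib
import json
import os
import re
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import __version__
from .fire import (
    BurnDateRaster,
    annual_composite,
    area_by_frequency,
    burn_frequency,
    burned_any_mask,
    repetitive_mask,
)
from .grid import Raster, check_aligned, mask_area_km2, pixel_area_km2
from .io import read_geojson, read_geotiff, write_geotiff
from .prioritize import (
    CriteriaStack,
    PriorityResult,
    RegionSet,
    criteria_count,
    select,
    summarize,
    zonal_tabulate,
)
from .protected import load_protected, rasterize_protected
from .terrain import compute_slope, steep_mask

__all__ = ["PipelineConfig", "StageError", "validate", "run"]

_YEAR_RE = re.compile(r"(\d{4})")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run.

    Paths: ``burn_dir`` holds one burn-date GeoTIFF per month (or per
    year) with a 4-digit year in the filename; ``dem_path``,
    ``protected_path``, ``regions_path``, ``land_path`` point to the DEM
    raster and the GeoJSON vectors. Thresholds default to the Greek
    configuration and are echoed into the run log.
    """

    burn_dir: str = ""
    dem_path: str = ""
    protected_path: str = ""
    regions_path: str = ""
    land_path: str = ""
    out_dir: str = "out"
    year_start: int = 2001
    year_end: int = 2023
    repetitive_threshold: int = 2
    slope_threshold_deg: float = 15.0
    steep_fraction_threshold: float = 0.5
    slope_order: str = "threshold_then_average"
    region_name_field: str = "name"
    analysis_crs: str = ""
    allow_gaps: bool = False

    def __post_init__(self) -> None:
        if self.repetitive_threshold < 1:
            raise ValueError("repetitive_threshold must be >= 1")
        if self.slope_threshold_deg <= 0:
            raise ValueError("slope_threshold_deg must be positive")
        if self.year_end < self.year_start:
            raise ValueError("empty year range")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _burn_files(cfg: PipelineConfig) -> dict[int, list[str]]:
    """Burn rasters grouped by the 4-digit year token in their filename."""
    files = sorted(
        glob.glob(os.path.join(cfg.burn_dir, "*.tif"))
        + glob.glob(os.path.join(cfg.burn_dir, "*.tiff"))
    )
    by_year: dict[int, list[str]] = {}
    for f in files:
        m = _YEAR_RE.search(os.path.basename(f))
        if not m:
            continue
        year = int(m.group(1))
        if cfg.year_start <= year <= cfg.year_end:
            by_year.setdefault(year, []).append(f)
    return by_year


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def validate(cfg: PipelineConfig) -> dict:
    """Pre-flight checks; returns ``{"fatal": [...], "warnings": [...]}``.

    Fatal findings: missing inputs, CRS mismatches, unaligned burn grids,
    a regions file without the configured name attribute, or (without
    ``allow_gaps``) missing years in the burn series.
    """
    fatal: list[str] = []
    warnings: list[str] = []

    by_year = _burn_files(cfg)
    if not by_year:
        fatal.append(f"no burn rasters with a year token found in {cfg.burn_dir!r}")
    else:
        missing = sorted(set(range(cfg.year_start, cfg.year_end + 1)) - set(by_year))
        if missing:
            msg = f"year gap in burn series: missing {missing}"
            (warnings if cfg.allow_gaps else fatal).append(msg)
        first = read_geotiff(next(iter(by_year.values()))[0])
        for year, files in by_year.items():
            for f in files:
                r = read_geotiff(f)
                if not check_aligned(first, r):
                    fatal.append(f"burn raster not aligned with series: {f}")
        if cfg.analysis_crs and first.grid.crs.upper() != cfg.analysis_crs.upper():
            fatal.append(
                f"burn series CRS {first.grid.crs} != analysis CRS {cfg.analysis_crs}"
            )

    if not cfg.dem_path or not os.path.exists(cfg.dem_path):
        fatal.append(f"DEM not found: {cfg.dem_path!r}")
    elif by_year:
        try:
            dem = read_geotiff(cfg.dem_path)
        except ValueError as exc:
            fatal.append(f"DEM unreadable: {exc}")
        else:
            first = read_geotiff(next(iter(by_year.values()))[0])
            if dem.grid.crs.strip().upper() != first.grid.crs.strip().upper():
                fatal.append(
                    f"DEM CRS {dem.grid.crs} != burn-series CRS {first.grid.crs}"
                )

    for label, path in (("protected", cfg.protected_path),
                        ("regions", cfg.regions_path),
                        ("land boundary", cfg.land_path)):
        if not path or not os.path.exists(path):
            fatal.append(f"{label} vector not found: {path!r}")

    if cfg.regions_path and os.path.exists(cfg.regions_path):
        _, props, _ = read_geojson(cfg.regions_path)
        if any(cfg.region_name_field not in p for p in props):
            fatal.append(
                f"regions file lacks the {cfg.region_name_field!r} attribute "
                "(config key region_name_field)"
            )

    return {"fatal": fatal, "warnings": warnings}


def _load_regions(cfg: PipelineConfig) -> RegionSet:
    geoms, props, _ = read_geojson(cfg.regions_path)
    return RegionSet(
        regions=[(str(p[cfg.region_name_field]), g) for g, p in zip(geoms, props)]
    )


def run(cfg: PipelineConfig) -> PriorityResult:
    """Execute the full prioritization pipeline and write all artifacts.

    Raises :class:`StageError` naming the failing stage; partial outputs
    are removed on failure.
    """
    report = validate(cfg)
    if report["fatal"]:
        raise StageError("validate", "; ".join(report["fatal"]))

    os.makedirs(cfg.out_dir, exist_ok=True)
    written: list[str] = []

    def _emit(name: str, raster: Raster) -> str:
        path = os.path.join(cfg.out_dir, name)
        write_geotiff(path, raster)
        written.append(path)
        return path

    log: dict = {
        "version": __version__,
        "config": asdict(cfg),
        "stages": [],
        "note": "all criteria evaluated on one pre-declared analysis grid; "
        "no implicit environment-driven resampling",
    }

    try:
        # --- fire history --------------------------------------------------
        try:
            by_year = _burn_files(cfg)
            composites: list[BurnDateRaster] = []
            for year in sorted(by_year):
                monthly = [read_geotiff(f, band="burn day-of-year")
                           for f in by_year[year]]
                composites.append(annual_composite(monthly, year))
            freq = burn_frequency(composites)
            grid = freq.grid
            burned_any = burned_any_mask(freq)
            repetitive = repetitive_mask(freq, cfg.repetitive_threshold)
            _emit("fire_frequency.tif", freq)
            _emit("repetitive_mask.tif", repetitive)
            freq_rows = area_by_frequency(freq)
            with open(os.path.join(cfg.out_dir, "area_by_frequency.csv"), "w") as fh:
                fh.write("frequency,pixel_count,area_km2\n")
                for r in freq_rows:
                    fh.write(f"{r['frequency']},{r['pixel_count']},{r['area_km2']:g}\n")
            written.append(os.path.join(cfg.out_dir, "area_by_frequency.csv"))
            log["stages"].append({
                "stage": "fire_history",
                "years": [min(by_year), max(by_year)],
                "burned_any_km2": mask_area_km2(burned_any),
                "repetitive_km2": mask_area_km2(repetitive),
            })
        except StageError:
            raise
        except Exception as exc:
            raise StageError("fire_history", str(exc)) from exc

        # --- terrain --------------------------------------------------------
        try:
            dem = read_geotiff(cfg.dem_path, band="elevation m")
            slope = compute_slope(dem)
            steep = steep_mask(
                slope, grid,
                threshold_deg=cfg.slope_threshold_deg,
                fraction_threshold=cfg.steep_fraction_threshold,
                order=cfg.slope_order,
            )
            _emit("slope.tif", slope)
            _emit("steep_mask.tif", steep)
            log["stages"].append({
                "stage": "terrain",
                "steep_km2": mask_area_km2(steep),
            })
        except StageError:
            raise
        except Exception as exc:
            raise StageError("terrain", f"{cfg.dem_path}: {exc}") from exc

        # --- protected ------------------------------------------------------
        try:
            land_geoms, _, _ = read_geojson(cfg.land_path)
            import shapely
            land = shapely.union_all(land_geoms)
            pas = load_protected(cfg.protected_path, land)
            protected = rasterize_protected(pas, grid)
            _emit("protected_mask.tif", protected)
            inv_path = os.path.join(cfg.out_dir, "protected_inventory.csv")
            with open(inv_path, "w") as fh:
                fh.write("name,designation,iucn_category,clipped_area_km2\n")
                for row in pas.inventory():
                    fh.write(
                        f"{row['name']},{row['designation']},"
                        f"{row['iucn_category']},{row['clipped_area_km2']:g}\n"
                    )
            written.append(inv_path)
            log["stages"].append({
                "stage": "protected",
                "n_polygons": len(pas),
                "protected_km2": mask_area_km2(protected),
            })
        except StageError:
            raise
        except Exception as exc:
            raise StageError("protected", f"{cfg.protected_path}: {exc}") from exc

        # --- prioritize -----------------------------------------------------
        try:
            stack = CriteriaStack(masks=[repetitive, steep, protected])
            count = criteria_count(stack)
            pre = select(count, "preselect")
            fin = select(count, "final")
            regions = _load_regions(cfg)
            table = zonal_tabulate(fin, regions)
            result = PriorityResult(
                criteria_count=count, preselection=pre, final=fin,
                region_table=table,
            )
            _emit("criteria_count.tif", count)
            _emit("preselection.tif", pre)
            _emit("final_priority.tif", fin)
            csv_text, summary_text = summarize(result)
            csv_path = os.path.join(cfg.out_dir, "region_table.csv")
            with open(csv_path, "w") as fh:
                fh.write(csv_text)
            written.append(csv_path)
            with open(os.path.join(cfg.out_dir, "summary.txt"), "w") as fh:
                fh.write(summary_text)
            written.append(os.path.join(cfg.out_dir, "summary.txt"))
            log["stages"].append({
                "stage": "prioritize",
                "preselection_km2": mask_area_km2(pre),
                "final_km2": mask_area_km2(fin),
                "pixel_area_km2": pixel_area_km2(grid),
            })
        except StageError:
            raise
        except Exception as exc:
            raise StageError("prioritize", str(exc)) from exc

        # --- run log --------------------------------------------------------
        checksums = {}
        for year in sorted(by_year):
            for f in by_year[year]:
                checksums[os.path.relpath(f, cfg.burn_dir)] = _sha256(f)
        for p in (cfg.dem_path, cfg.protected_path, cfg.regions_path, cfg.land_path):
            checksums[os.path.basename(p)] = _sha256(p)
        log["input_checksums"] = checksums
        with open(os.path.join(cfg.out_dir, "run_log.json"), "w") as fh:
            json.dump(log, fh, indent=1, sort_keys=True)
        return result
    except StageError:
        for p in written:
            if os.path.exists(p):
                os.remove(p)
        raise
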