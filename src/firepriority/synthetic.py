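"""Self-contained synthetic scenarios with planted ground truth.

A scenario stands in for the real inputs of the prioritization pipeline —
a multi-year monthly burn-date series (MCD64A1-like, 500 m), a fine DEM
(Copernicus-like, 30 m), protected-area polygons and an administrative
region partition — with full knowledge of which pixels should survive
each stage:

* ``planted`` pixels are forced to satisfy all three criteria (burned in
  at least two distinct years, sitting on a >15° ramp, covered by a
  protected rectangle);
* ``decoys`` are forced to satisfy exactly 0, 1 or 2 named criteria and
  nothing more: random fire is suppressed at control pixels that must
  not meet the fire criterion, and steep/protected patches are placed
  only at control pixels that must meet those criteria.

Because slope and protection are deterministic given the scenario and
fire is overridden at every control pixel, the final 3-of-3 mask of a
correct pipeline equals the planted set exactly, whatever the random
background fire does — background pixels can meet at most the fire
criterion. This truth-recovery property is what end-to-end tests check.

Randomness comes from one `numpy` Generator seeded once per scenario and
consumed in a fixed documented order (per-year burn draws, then
day-of-year draws), so changing polygon specs never perturbs the fire
realization.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import box

from .fire import BurnDateRaster
from .grid import GridSpec, Raster
from .prioritize import RegionSet
from .protected import ProtectedArea, ProtectedAreaSet

__all__ = ["SyntheticScenario", "make_fire_series", "make_dem", "make_vectors",
           "write_scenario", "MONTH_START_DOY"]

#: first day of year of each month, non-leap (month 1..12); month m spans
#: [MONTH_START_DOY[m-1], MONTH_START_DOY[m]) with a sentinel 366 at the end
MONTH_START_DOY = (1, 32, 60, 91, 121, 152, 182, 213, 244, 274, 305, 335, 366)

# default control-pixel layout on the 60x60 analysis grid (row, col);
# spaced >= 4 cells apart so steep-patch margins never reach a neighbour
_DEFAULT_PLANTED = ((10, 10), (40, 40))
_DEFAULT_DECOYS = {
    # exactly two criteria
    "fire_slope": ((10, 30),),
    "fire_protected": ((30, 10),),
    "slope_protected": ((30, 30),),
    # exactly one criterion
    "fire_only": ((50, 20),),
    "slope_only": ((20, 50),),
    "protected_only": ((50, 50),),
    # exactly zero criteria (fire suppressed, flat, unprotected)
    "none": ((5, 50),),
}


@dataclass
class SyntheticScenario:
    """Parameters that rebuild a scenario bit-identically from the seed.

    The default geometry mirrors the real configuration at desk scale: a
    60×60 analysis grid at 500 m (30 km × 30 km) with a nested 1000×1000
    fine grid at 30 m sharing the origin, 23 annual time steps, a 5%
    baseline per-pixel annual burn probability with spatial clustering.
    """

    seed: int = 0
    crs: str = "EPSG:2100"
    origin_x: float = 300000.0
    origin_y: float = 4500000.0
    n_rows: int = 60
    n_cols: int = 60
    cell_size: float = 500.0
    fine_cell_size: float = 30.0
    year_start: int = 2001
    year_end: int = 2023
    burn_prob_base: float = 0.05
    hotspots: tuple = ()  # (row, col, radius_cells, extra_probability)
    smoothing_len: float = 3.0  # correlation length, analysis cells
    base_gradient: float = math.tan(math.radians(5.0))   # background slope 5 deg
    steep_gradient: float = math.tan(math.radians(25.0))  # patch slope 25 deg
    planted: tuple = _DEFAULT_PLANTED
    decoys: dict = field(default_factory=lambda: {k: tuple(v) for k, v in _DEFAULT_DECOYS.items()})
    region_split: tuple = (2, 2)  # regions as an r x c partition of the grid

    def __post_init__(self) -> None:
        if not 0.0 <= self.burn_prob_base <= 1.0:
            raise ValueError("burn_prob_base must be in [0, 1]")
        for r, c in self.all_control_pixels():
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise ValueError(f"control pixel {(r, c)} outside grid")
        seen = set()
        for px in self.all_control_pixels():
            if px in seen:
                raise ValueError(f"control pixel {px} used twice")
            seen.add(px)

    # --- derived geometry ---------------------------------------------------

    @property
    def years(self) -> list[int]:
        return list(range(self.year_start, self.year_end + 1))

    def analysis_grid(self) -> GridSpec:
        return GridSpec(self.crs, self.origin_x, self.origin_y,
                        self.cell_size, self.cell_size, self.n_rows, self.n_cols)

    def fine_grid(self) -> GridSpec:
        extent_x = self.n_cols * self.cell_size
        extent_y = self.n_rows * self.cell_size
        return GridSpec(
            self.crs, self.origin_x, self.origin_y,
            self.fine_cell_size, self.fine_cell_size,
            int(round(extent_y / self.fine_cell_size)),
            int(round(extent_x / self.fine_cell_size)),
        )

    # --- control-pixel bookkeeping -------------------------------------------

    def decoy_pixels(self, *kinds: str) -> list[tuple[int, int]]:
        return [px for k in kinds for px in self.decoys.get(k, ())]

    def all_control_pixels(self) -> list[tuple[int, int]]:
        return list(self.planted) + self.decoy_pixels(*self.decoys.keys())

    def fire_forced(self) -> list[tuple[int, int]]:
        """Control pixels that must burn in >= 2 distinct years."""
        return list(self.planted) + self.decoy_pixels(
            "fire_slope", "fire_protected", "fire_only"
        )

    def fire_suppressed(self) -> list[tuple[int, int]]:
        """Control pixels where random burns are removed entirely."""
        return self.decoy_pixels(
            "slope_protected", "slope_only", "protected_only", "none"
        )

    def steep_pixels(self) -> list[tuple[int, int]]:
        return list(self.planted) + self.decoy_pixels(
            "fire_slope", "slope_protected", "slope_only"
        )

    def protected_pixels(self) -> list[tuple[int, int]]:
        return list(self.planted) + self.decoy_pixels(
            "fire_protected", "slope_protected", "protected_only"
        )

    def two_criteria_pixels(self) -> list[tuple[int, int]]:
        return self.decoy_pixels("fire_slope", "fire_protected", "slope_protected")

    def truth(self) -> dict:
        return {
            "planted": [list(p) for p in self.planted],
            "decoys": {k: [list(p) for p in v] for k, v in self.decoys.items()},
        }


# --- fires -------------------------------------------------------------------


def _burn_probability(s: SyntheticScenario, rng: np.random.Generator) -> np.ndarray:
    """Spatially clustered per-pixel annual burn probability field.

    White noise smoothed at ``smoothing_len`` modulates the base rate in
    logit space (so the base stays the median rate and the degenerate
    rates 0 and 1 are preserved exactly), mimicking the spatial
    contiguity of satellite burned-area maps; hotspots add local
    probability bumps.
    """
    from scipy.special import expit, logit

    noise = rng.standard_normal((s.n_rows, s.n_cols))
    if s.smoothing_len > 0:
        smooth = ndimage.gaussian_filter(noise, s.smoothing_len, mode="nearest")
        # restore unit variance so base probability stays the median rate
        sd = smooth.std()
        if sd > 0:
            smooth /= sd
    else:
        smooth = noise
    if s.burn_prob_base in (0.0, 1.0):
        p = np.full((s.n_rows, s.n_cols), s.burn_prob_base)
    else:
        p = expit(logit(s.burn_prob_base) + 0.5 * smooth)
    for (r, c, radius, extra) in s.hotspots:
        rr, cc = np.ogrid[: s.n_rows, : s.n_cols]
        p = np.where((rr - r) ** 2 + (cc - c) ** 2 <= radius**2, p + extra, p)
    return np.clip(p, 0.0, 1.0)


def make_fire_series(s: SyntheticScenario) -> list[list[BurnDateRaster]]:
    """Monthly burn-date rasters for every scenario year.

    Returns one list of 12 monthly rasters per year (calendar order).
    Per year: Bernoulli burns from the clustered probability field, a
    uniform day-of-year 1..365 for each burned pixel, placed in the raster
    of the containing month. Fire-forced control pixels burn in the first
    two scenario years at least; fire-suppressed ones never burn.
    """
    rng = np.random.default_rng(s.seed)
    grid = s.analysis_grid()
    forced = s.fire_forced()
    suppressed = s.fire_suppressed()

    series: list[list[BurnDateRaster]] = []
    for iy, year in enumerate(s.years):
        # draw order per year: probability noise, burn draws, DOY draws
        p = _burn_probability(s, rng)
        burned = rng.random((s.n_rows, s.n_cols)) < p
        doy = rng.integers(1, 366, size=(s.n_rows, s.n_cols))
        for (r, c) in suppressed:
            burned[r, c] = False
        if iy < 2:  # plant >= 2 distinct burn years
            for (r, c) in forced:
                burned[r, c] = True

        months = []
        for m in range(1, 13):
            lo, hi = MONTH_START_DOY[m - 1], MONTH_START_DOY[m]
            vals = np.where(burned & (doy >= lo) & (doy < hi), doy, 0).astype(np.int16)
            months.append(
                BurnDateRaster(grid, vals, nodata=None,
                               band="burn day-of-year", year=year)
            )
        series.append(months)
    return series


# --- DEM ---------------------------------------------------------------------


def _steep_zone_fine_cols(s: SyntheticScenario, col: int, margin: int = 2) -> tuple[int, int]:
    ratio = s.cell_size / s.fine_cell_size
    lo = int(math.floor(col * ratio)) - margin
    hi = int(math.ceil((col + 1) * ratio)) + margin
    return max(lo, 0), min(hi, s.fine_grid().n_cols)


def _steep_zone_fine_rows(s: SyntheticScenario, row: int, margin: int = 2) -> tuple[int, int]:
    ratio = s.cell_size / s.fine_cell_size
    lo = int(math.floor(row * ratio)) - margin
    hi = int(math.ceil((row + 1) * ratio)) + margin
    return max(lo, 0), min(hi, s.fine_grid().n_rows)


def make_dem(s: SyntheticScenario) -> Raster:
    """Fine-grid DEM: a gentle eastward base ramp (below the slope
    threshold) with steeper ramp patches over every control pixel that
    must satisfy the slope criterion.

    Each steep patch covers the footprint of its analysis cell plus a
    two-fine-cell margin, so after strict thresholding at 15° and
    majority aggregation exactly the intended analysis cells are steep:
    the margin contributes well under half of any neighbouring cell.
    Patch gradients are exact, so Horn slope inside a patch equals
    ``arctan(steep_gradient)`` analytically.
    """
    fg = s.fine_grid()
    x = (np.arange(fg.n_cols) + 0.5) * fg.cell_size_x
    z = np.tile(s.base_gradient * x, (fg.n_rows, 1))
    for (r, c) in s.steep_pixels():
        r0, r1 = _steep_zone_fine_rows(s, r)
        c0, c1 = _steep_zone_fine_cols(s, c)
        xo = (c0 + 0.5) * fg.cell_size_x
        z[r0:r1, c0:c1] = (
            s.base_gradient * xo + s.steep_gradient * (x[c0:c1] - xo)
        )
    return Raster(fg, z, nodata=None, band="elevation m")


# --- vectors -----------------------------------------------------------------


def _cell_box(grid: GridSpec, row: int, col: int,
              pad_cells: float = 0.0) -> shapely.Polygon:
    x0 = grid.origin_x + (col - pad_cells) * grid.cell_size_x
    x1 = grid.origin_x + (col + 1 + pad_cells) * grid.cell_size_x
    y1 = grid.origin_y - (row - pad_cells) * grid.cell_size_y
    y0 = grid.origin_y - (row + 1 + pad_cells) * grid.cell_size_y
    return box(x0, y0, x1, y1)


def make_vectors(
    s: SyntheticScenario,
) -> tuple[ProtectedAreaSet, RegionSet, shapely.Polygon]:
    """Protected polygons, an exact region partition, and the land boundary.

    Protected rectangles coincide with the analysis-cell footprints of
    the control pixels that must meet the protection criterion, so the
    center rule selects exactly those cells. Regions split the grid into
    a ``region_split`` checkerboard of named rectangles; the land
    boundary is the grid envelope.
    """
    grid = s.analysis_grid()
    areas = [
        ProtectedArea(
            geometry=_cell_box(grid, r, c),
            name=f"synthetic-PA-{r}-{c}",
            designation="synthetic reserve",
            iucn_category="Not Reported",
        )
        for (r, c) in s.protected_pixels()
    ]
    pas = ProtectedAreaSet(areas=areas, crs=s.crs)

    nr, nc = s.region_split
    if s.n_rows % nr or s.n_cols % nc:
        raise ValueError("region_split must evenly partition the grid")
    rstep, cstep = s.n_rows // nr, s.n_cols // nc
    regions = []
    for i in range(nr):
        for j in range(nc):
            x0 = grid.origin_x + j * cstep * grid.cell_size_x
            x1 = grid.origin_x + (j + 1) * cstep * grid.cell_size_x
            y1 = grid.origin_y - i * rstep * grid.cell_size_y
            y0 = grid.origin_y - (i + 1) * rstep * grid.cell_size_y
            regions.append((f"region-{i}-{j}", box(x0, y0, x1, y1)))
    region_set = RegionSet(regions=regions)

    minx, miny, maxx, maxy = grid.bounds()
    land = box(minx, miny, maxx, maxy)
    return pas, region_set, land


# --- scenario directory ------------------------------------------------------


def write_scenario(s: SyntheticScenario, out_dir: str | os.PathLike) -> dict:
    """Materialize a scenario on disk: monthly burn GeoTIFFs, the DEM,
    protected/region/land GeoJSON, and ``truth.json``.

    Returns a manifest of the paths written (also saved as
    ``scenario.json`` next to the data).
    """
    from .io import write_geojson, write_geotiff

    out = os.fspath(out_dir)
    burn_dir = os.path.join(out, "burn")
    os.makedirs(burn_dir, exist_ok=True)

    for months in make_fire_series(s):
        for m, raster in enumerate(months, start=1):
            write_geotiff(
                os.path.join(burn_dir, f"burndate_{raster.year}_{m:02d}.tif"),
                raster,
            )
    write_geotiff(os.path.join(out, "dem.tif"), make_dem(s))

    pas, regions, land = make_vectors(s)
    write_geojson(
        os.path.join(out, "protected.geojson"),
        pas.geometries(),
        [
            {"name": a.name, "designation": a.designation,
             "iucn_category": a.iucn_category}
            for a in pas.areas
        ],
        crs=s.crs,
    )
    write_geojson(
        os.path.join(out, "regions.geojson"),
        [g for _, g in regions.regions],
        [{"name": n} for n, _ in regions.regions],
        crs=s.crs,
    )
    write_geojson(os.path.join(out, "land.geojson"), [land], [{}], crs=s.crs)

    with open(os.path.join(out, "truth.json"), "w") as fh:
        json.dump(s.truth(), fh, indent=1)

    manifest = {
        "scenario": asdict(s),
        "burn_dir": burn_dir,
        "dem": os.path.join(out, "dem.tif"),
        "protected": os.path.join(out, "protected.geojson"),
        "regions": os.path.join(out, "regions.geojson"),
        "land": os.path.join(out, "land.geojson"),
        "truth": os.path.join(out, "truth.json"),
    }
    with open(os.path.join(out, "scenario.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
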