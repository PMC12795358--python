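"""Slope from a DEM (Horn's method) and the steep-slope criterion.

Slope is computed with Horn's 3×3 weighted finite differences — the
algorithm behind the slope tools of standard GIS software, exact on
planar surfaces:

    dz/dx = ((c + 2f + i) - (a + 2d + g)) / (8 * cell_x)
    dz/dy = ((g + 2h + i) - (a + 2b + c)) / (8 * cell_y)
    slope = arctan(sqrt((dz/dx)² + (dz/dy)²))          [degrees]

for the 3×3 window ``a b c / d e f / g h i`` (rows north→south, columns
west→east, y decreasing with row index). Border pixels are computed after
edge replication so coastal cells stay usable; a pixel is nodata if any
cell of its window is nodata.

The criterion mask binarizes slope strictly above a threshold (default
15°, the landslide-susceptibility bound used for Greek terrain) on the
fine DEM grid, aggregates the binary mask to the analysis grid by
area-weighted averaging, and re-binarizes at a majority fraction.
"""

from __future__ import annotations

import numpy as np

from .grid import GridSpec, Raster, aggregate_mean, threshold_mask

__all__ = ["compute_slope", "steep_mask"]


def compute_slope(dem: Raster) -> Raster:
    """Slope angle in degrees from an elevation raster (Horn's method).

    Raises
    ------
    ValueError
        if the DEM grid is geographic (degree units) or smaller than the
        3×3 kernel.
    """
    g = dem.grid
    if g.is_geographic:
        raise ValueError(
            f"compute_slope: DEM CRS {g.crs!r} uses degrees; reproject to meters"
        )
    if g.n_rows < 3 or g.n_cols < 3:
        raise ValueError("compute_slope: DEM must be at least 3x3")

    z = np.asarray(dem.values, dtype=float)
    bad = dem.nodata_mask() | ~np.isfinite(z)
    zp = np.pad(np.where(bad, 0.0, z), 1, mode="edge")
    badp = np.pad(bad, 1, mode="edge")

    a, b, c = zp[:-2, :-2], zp[:-2, 1:-1], zp[:-2, 2:]
    d, f = zp[1:-1, :-2], zp[1:-1, 2:]
    gg, h, i = zp[2:, :-2], zp[2:, 1:-1], zp[2:, 2:]

    dzdx = ((c + 2 * f + i) - (a + 2 * d + gg)) / (8 * g.cell_size_x)
    dzdy = ((gg + 2 * h + i) - (a + 2 * b + c)) / (8 * g.cell_size_y)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))

    # any nodata in the 3x3 window poisons the center pixel
    win_bad = np.zeros_like(bad)
    for dr in (0, 1, 2):
        for dc in (0, 1, 2):
            win_bad |= badp[dr : dr + g.n_rows, dc : dc + g.n_cols]
    slope[win_bad] = np.nan
    return Raster(g, slope, nodata=float("nan"), band="slope degrees")


def steep_mask(
    slope: Raster,
    analysis_grid: GridSpec,
    threshold_deg: float = 15.0,
    fraction_threshold: float = 0.5,
    order: str = "threshold_then_average",
) -> Raster:
    """Steep-slope criterion on the analysis grid.

    Default order (``threshold_then_average``): binarize slope strictly
    above ``threshold_deg`` on the fine grid, aggregate the 0/1 mask to
    ``analysis_grid`` by area-weighted mean, then mark a coarse cell steep
    when the steep fraction is >= ``fraction_threshold``. The alternative
    (``average_then_threshold``) averages the slope angle first and
    thresholds the coarse mean — exposed for sensitivity runs, since GIS
    "spatial averaging" workflows are ambiguous between the two.

    If the slope raster is already on the analysis grid it is thresholded
    directly.
    """
    if order not in ("threshold_then_average", "average_then_threshold"):
        raise ValueError(f"steep_mask: unknown order {order!r}")

    same_grid = slope.grid.shape == analysis_grid.shape and (
        slope.grid.cell_size_x == analysis_grid.cell_size_x
        and slope.grid.cell_size_y == analysis_grid.cell_size_y
    )
    if same_grid:
        return threshold_mask(slope, threshold_deg, strict=True, label="steep_slope")

    if order == "threshold_then_average":
        fine_mask = threshold_mask(slope, threshold_deg, strict=True)
        frac = aggregate_mean(
            Raster(slope.grid, fine_mask.values.astype(float),
                   nodata=float(fine_mask.nodata), band="steep fraction"),
            analysis_grid,
        )
        # 255 sentinel cells were excluded via nodata; re-binarize the fraction
        return threshold_mask(frac, fraction_threshold, strict=False,
                              label="steep_slope")
    coarse = aggregate_mean(slope, analysis_grid)
    return threshold_mask(coarse, threshold_deg, strict=True, label="steep_slope")
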