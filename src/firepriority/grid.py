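"""Raster grid model: alignment, aggregation, thresholding, area accounting.

Every stage of the prioritization pipeline works on rasters tied to a
:class:`GridSpec` — a projected, meter-unit grid with a fixed origin and
cell size. All overlay operations refuse inputs whose grids are not
aligned, so resolution harmonization (30 m DEM products onto the 500 m
analysis grid) must go through :func:`aggregate_mean` explicitly.

Conventions
-----------
* ``origin_x, origin_y`` are the coordinates of the *outer* (top-left)
  corner of pixel ``(0, 0)``; rows increase downward (decreasing y),
  columns increase eastward (increasing x), as in GeoTIFF.
* Nodata is carried per raster: ``NaN`` for float rasters and an explicit
  sentinel for integer rasters; boolean masks are uint8 ``{0, 1, 255}``
  with 255 = nodata. Operations propagate nodata, never treat it as 0
  unless documented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GridSpec",
    "Raster",
    "AlignmentError",
    "MASK_NODATA",
    "check_aligned",
    "aggregate_mean",
    "threshold_mask",
    "pixel_area_km2",
]

#: nodata sentinel for uint8 boolean masks
MASK_NODATA = 255

#: relative tolerance (fraction of a cell) for origin-alignment checks
ALIGN_RTOL = 1e-6

# CRS identifiers treated as geographic (degree units); everything else is
# assumed projected in meters. Without a full CRS database this heuristic
# covers the identifiers that plausibly reach this pipeline.
_GEOGRAPHIC_IDS = {"EPSG:4326", "EPSG:4258", "OGC:CRS84", "CRS84"}


class AlignmentError(ValueError):
    """Raised when an overlay receives rasters on incompatible grids."""


def _is_geographic(crs: str) -> bool:
    c = crs.strip().upper()
    return c in _GEOGRAPHIC_IDS or c.startswith("GEOGCS")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of an analysis raster: projected CRS, origin, cell size, shape.

    Parameters
    ----------
    crs : str
        Identifier of a projected CRS in meter units, e.g. ``"EPSG:2100"``
        (Greek Grid). Geographic (degree) identifiers are accepted at
        construction but rejected by area computations.
    origin_x, origin_y : float
        Map coordinates of the outer top-left corner of pixel (0, 0).
    cell_size_x, cell_size_y : float
        Positive pixel edge lengths in CRS units (meters).
    n_rows, n_cols : int
        Raster dimensions.
    """

    crs: str
    origin_x: float
    origin_y: float
    cell_size_x: float
    cell_size_y: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size_x <= 0 or self.cell_size_y <= 0:
            raise ValueError("cell sizes must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def is_geographic(self) -> bool:
        return _is_geographic(self.crs)

    # --- coordinate helpers -------------------------------------------------

    def x_edges(self) -> np.ndarray:
        """Column edge x-coordinates, length n_cols + 1, increasing."""
        return self.origin_x + self.cell_size_x * np.arange(self.n_cols + 1)

    def y_edges(self) -> np.ndarray:
        """Row edge y-coordinates, length n_rows + 1, decreasing."""
        return self.origin_y - self.cell_size_y * np.arange(self.n_rows + 1)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinate arrays of shape (n_rows, n_cols)."""
        xs = self.origin_x + self.cell_size_x * (np.arange(self.n_cols) + 0.5)
        ys = self.origin_y - self.cell_size_y * (np.arange(self.n_rows) + 0.5)
        return np.meshgrid(xs, ys)

    def bounds(self) -> tuple[float, float, float, float]:
        """(min_x, min_y, max_x, max_y) of the grid envelope."""
        return (
            self.origin_x,
            self.origin_y - self.cell_size_y * self.n_rows,
            self.origin_x + self.cell_size_x * self.n_cols,
            self.origin_y,
        )

    def with_shape(self, n_rows: int, n_cols: int) -> "GridSpec":
        return replace(self, n_rows=n_rows, n_cols=n_cols)


@dataclass
class Raster:
    """A single-band raster bound to a :class:`GridSpec`.

    ``values`` has shape ``grid.shape``; ``nodata`` is the sentinel used in
    ``values`` (NaN allowed for float rasters), or ``None`` if the raster
    is complete. ``band`` is a free-text label, e.g. ``"slope degrees"``.
    """

    grid: GridSpec
    values: np.ndarray
    nodata: float | int | None = None
    band: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    def nodata_mask(self) -> np.ndarray:
        """Boolean array, True where the cell is nodata."""
        if self.nodata is None:
            return np.zeros(self.grid.shape, dtype=bool)
        if isinstance(self.nodata, float) and math.isnan(self.nodata):
            return np.isnan(self.values)
        return self.values == self.nodata

    def valid_values(self) -> np.ndarray:
        return self.values[~self.nodata_mask()]


def _offsets_are_multiples(delta: float, cell: float) -> bool:
    frac = abs(delta / cell - round(delta / cell))
    return frac <= ALIGN_RTOL


def check_aligned(a: Raster | GridSpec, b: Raster | GridSpec) -> bool:
    """True iff the two grids share CRS and cell size, and their origins
    differ by integer multiples of the cell size.

    Aligned grids may have different extents; their pixel lattices coincide
    where they overlap, which is what pixelwise overlay requires.
    """
    ga = a.grid if isinstance(a, Raster) else a
    gb = b.grid if isinstance(b, Raster) else b
    if ga.crs.strip().upper() != gb.crs.strip().upper():
        return False
    if not math.isclose(ga.cell_size_x, gb.cell_size_x, rel_tol=ALIGN_RTOL):
        return False
    if not math.isclose(ga.cell_size_y, gb.cell_size_y, rel_tol=ALIGN_RTOL):
        return False
    return _offsets_are_multiples(
        ga.origin_x - gb.origin_x, ga.cell_size_x
    ) and _offsets_are_multiples(ga.origin_y - gb.origin_y, ga.cell_size_y)


def require_aligned(*rasters: Raster, what: str = "overlay") -> None:
    """Raise :class:`AlignmentError` unless all rasters share one grid."""
    first = rasters[0]
    for r in rasters[1:]:
        if r.grid.shape != first.grid.shape or not check_aligned(first, r):
            raise AlignmentError(f"{what}: rasters are not on a common grid")


def _overlap_weights(fine_edges: np.ndarray, coarse_edges: np.ndarray,
                     descending: bool = False) -> np.ndarray:
    """1-D interval-overlap matrix W[c, f] = |coarse cell c ∩ fine cell f|.

    Edge arrays are monotone (increasing for x, decreasing for y when
    ``descending``). Used to express area-weighted aggregation as two
    matrix products, one per axis.
    """
    if descending:
        fine_edges = -fine_edges
        coarse_edges = -coarse_edges
    f_lo, f_hi = fine_edges[:-1], fine_edges[1:]
    c_lo, c_hi = coarse_edges[:-1, None], coarse_edges[1:, None]
    overlap = np.minimum(f_hi[None, :], c_hi) - np.maximum(f_lo[None, :], c_lo)
    return np.clip(overlap, 0.0, None)


def aggregate_mean(fine: Raster, coarse_grid: GridSpec) -> Raster:
    """Area-weighted mean of a fine raster onto a strictly coarser grid.

    Each coarse cell receives the mean of the fine cells overlapping its
    footprint, weighted by overlap area — the "spatial averaging" used to
    bring a 30 m product onto the 500 m analysis grid. Non-integer
    resolution ratios (500/30) are handled exactly via interval overlap.
    Nodata fine cells are excluded from the mean; a coarse cell whose
    footprint contains no valid fine data is NaN (nodata).

    Raises
    ------
    AlignmentError
        if the CRSs differ.
    ValueError
        if the coarse cell size is not strictly larger than the fine one.
    """
    fg = fine.grid
    if fg.crs.strip().upper() != coarse_grid.crs.strip().upper():
        raise AlignmentError("aggregate_mean: CRS mismatch between grids")
    if coarse_grid.cell_size_x <= fg.cell_size_x or coarse_grid.cell_size_y <= fg.cell_size_y:
        raise ValueError("aggregate_mean: coarse grid must have strictly larger cells")

    wx = _overlap_weights(fg.x_edges(), coarse_grid.x_edges())          # (Cc, Fc)
    wy = _overlap_weights(fg.y_edges(), coarse_grid.y_edges(), True)    # (Cr, Fr)

    vals = np.asarray(fine.values, dtype=float)
    invalid = fine.nodata_mask() | ~np.isfinite(vals)
    weights = np.where(invalid, 0.0, 1.0)
    vals = np.where(invalid, 0.0, vals)

    num = wy @ (vals * weights) @ wx.T
    den = wy @ weights @ wx.T
    out = np.full(coarse_grid.shape, np.nan)
    np.divide(num, den, out=out, where=den > 0)
    return Raster(coarse_grid, out, nodata=float("nan"), band=fine.band)


def threshold_mask(r: Raster, threshold: float, strict: bool = True,
                   label: str = "") -> Raster:
    """Binarize a numeric raster: 1 where value > threshold (``strict``)
    or >= threshold, else 0; nodata propagates as 255.
    """
    vals = np.asarray(r.values, dtype=float)
    hot = vals > threshold if strict else vals >= threshold
    out = hot.astype(np.uint8)
    bad = r.nodata_mask() | ~np.isfinite(vals)
    out[bad] = MASK_NODATA
    return Raster(r.grid, out, nodata=MASK_NODATA, band=label or r.band)


def pixel_area_km2(grid: GridSpec) -> float:
    """Projected area of one pixel in km² (cell_x × cell_y / 10⁶).

    Raises
    ------
    ValueError
        for geographic (degree-unit) CRSs — reproject to an equal-area or
        national meter-unit CRS before area accounting.
    """
    if grid.is_geographic:
        raise ValueError(
            f"pixel_area_km2: grid CRS {grid.crs!r} uses degrees; "
            "reproject inputs to a projected meter-unit CRS first"
        )
    return grid.cell_size_x * grid.cell_size_y / 1e6


def mask_area_km2(mask: Raster) -> float:
    """Area of the 1-pixels of a boolean mask: count × pixel area."""
    n = int(np.sum(mask.values == 1))
    return n * pixel_area_km2(mask.grid)
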