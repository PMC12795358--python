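"""Multi-criteria overlay, priority selection and per-region tabulation.

The three aligned boolean criterion masks — repetitive fire, steep slope,
protected area — are summed per pixel into a 0..3 criteria count.
Preselection keeps pixels meeting at least two criteria; the final
priority map keeps pixels meeting all three (the elementwise AND of the
masks). Areas are then tabulated per administrative region by assigning
each selected pixel center to exactly one region polygon, so regional
pixel counts plus the unassigned remainder always conserve the total.

Nodata in one criterion scores as "criterion not met" for that pixel
rather than poisoning it; a pixel with nodata in all three criteria is
nodata in the count raster.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

from .grid import MASK_NODATA, Raster, pixel_area_km2, require_aligned

__all__ = [
    "CRITERIA_LABELS",
    "CriteriaStack",
    "RegionSet",
    "PriorityResult",
    "criteria_count",
    "select",
    "zonal_tabulate",
    "focus_area_km2",
    "summarize",
]

CRITERIA_LABELS = ("repetitive_fire", "steep_slope", "protected_area")

#: nodata sentinel for the int criteria-count raster
COUNT_NODATA = -1

UNASSIGNED = "_unassigned"


class StackError(ValueError):
    """Criteria stack is mislabeled or not aligned."""


@dataclass
class CriteriaStack:
    """Exactly three aligned criterion masks with the canonical labels."""

    masks: list[Raster]

    def __post_init__(self) -> None:
        labels = sorted(m.band for m in self.masks)
        if labels != sorted(CRITERIA_LABELS):
            raise StackError(
                f"criteria stack needs labels {CRITERIA_LABELS}, got {labels}"
            )
        try:
            require_aligned(*self.masks, what="criteria stack")
        except ValueError as exc:
            raise StackError(str(exc)) from exc

    def __getitem__(self, label: str) -> Raster:
        for m in self.masks:
            if m.band == label:
                return m
        raise KeyError(label)


@dataclass
class RegionSet:
    """Named administrative-region polygons (e.g. the 14 Greek regions)."""

    regions: list[tuple[str, BaseGeometry]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.regions]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate region names: {dupes}")

    def names(self) -> list[str]:
        return [n for n, _ in self.regions]


@dataclass
class PriorityResult:
    """Outputs of the overlay stage plus the regional area table."""

    criteria_count: Raster
    preselection: Raster
    final: Raster
    region_table: list[dict[str, Any]] = field(default_factory=list)

    @property
    def total_area_km2(self) -> float:
        return int(np.sum(self.final.values == 1)) * pixel_area_km2(self.final.grid)


def criteria_count(stack: CriteriaStack) -> Raster:
    """Per-pixel number of satisfied criteria (0..3).

    Nodata in a mask counts as 0 for that criterion; pixels nodata in all
    three masks are nodata in the output.
    """
    met = np.zeros(stack.masks[0].grid.shape, dtype=np.int16)
    all_nodata = np.ones_like(met, dtype=bool)
    for m in stack.masks:
        bad = m.nodata_mask()
        met += ((np.asarray(m.values) == 1) & ~bad).astype(np.int16)
        all_nodata &= bad
    met[all_nodata] = COUNT_NODATA
    return Raster(stack.masks[0].grid, met, nodata=COUNT_NODATA,
                  band="criteria count")


def select(count: Raster, mode: str) -> Raster:
    """Priority selection from the criteria count.

    ``mode="preselect"``: count >= 2 (two-of-three, the preliminary map).
    ``mode="final"``: count == 3 (all criteria met).
    """
    if mode not in ("preselect", "final"):
        raise ValueError(f"select: mode must be 'preselect' or 'final', got {mode!r}")
    vals = np.asarray(count.values)
    bad = count.nodata_mask()
    if np.any((~bad) & ((vals < 0) | (vals > 3))):
        raise ValueError("select: criteria count outside 0..3")
    hot = vals >= 2 if mode == "preselect" else vals == 3
    out = (hot & ~bad).astype(np.uint8)
    out[bad] = MASK_NODATA
    return Raster(count.grid, out, nodata=MASK_NODATA,
                  band="preselection" if mode == "preselect" else "final_priority")


def zonal_tabulate(mask: Raster, regions: RegionSet) -> list[dict[str, Any]]:
    """Count mask-1 pixels per region (pixel-center containment) and
    convert to km².

    Every region appears in the output, zero-count ones included; pixels
    whose centers fall outside all regions are reported under
    ``"_unassigned"``. A center on a shared boundary is assigned to the
    first containing region in the stable input order, so the rows always
    partition the selected pixels:  Σ counts + unassigned = total.
    """
    px = pixel_area_km2(mask.grid)
    xs, ys = mask.grid.cell_centers()
    sel = np.asarray(mask.values) == 1
    x_sel, y_sel = xs[sel], ys[sel]
    unclaimed = np.ones(x_sel.shape, dtype=bool)

    rows = []
    for name, geom in regions.regions:
        hit = np.zeros(x_sel.shape, dtype=bool)
        if unclaimed.any() and not geom.is_empty:
            # boundary-inclusive test so shared-edge centers are claimed;
            # the unclaimed filter keeps the assignment exclusive
            hit = unclaimed & shapely.intersects_xy(geom, x_sel, y_sel)
            unclaimed &= ~hit
        n = int(hit.sum())
        rows.append({"region": name, "pixel_count": n, "area_km2": n * px})
    n_un = int(unclaimed.sum())
    rows.append({"region": UNASSIGNED, "pixel_count": n_un, "area_km2": n_un * px})
    return rows


def focus_area_km2(mask: Raster, polygon: BaseGeometry) -> float:
    """Area of the mask's 1-pixels whose centers fall in a focus polygon
    (site-report helper, e.g. a single protected area or island)."""
    xs, ys = mask.grid.cell_centers()
    sel = np.asarray(mask.values) == 1
    inside = shapely.intersects_xy(polygon, xs[sel], ys[sel])
    return int(inside.sum()) * pixel_area_km2(mask.grid)


def summarize(result: PriorityResult) -> tuple[str, str]:
    """Render the regional table as CSV and a human-readable summary.

    CSV rows (region, pixel_count, area_km2) are sorted by area
    descending with a TOTAL row appended; the text summary reports the
    national total, the number of regions with nonzero selected area, and
    a conservation check between the table and the final mask.
    """
    rows = [r for r in result.region_table if r["region"] != UNASSIGNED]
    unassigned = next(
        (r for r in result.region_table if r["region"] == UNASSIGNED),
        {"pixel_count": 0, "area_km2": 0.0},
    )
    rows = sorted(rows, key=lambda r: (-r["area_km2"], r["region"]))
    total_px = sum(r["pixel_count"] for r in result.region_table)
    total_km2 = sum(r["area_km2"] for r in result.region_table)

    buf = _io.StringIO()
    buf.write("region,pixel_count,area_km2\n")
    for r in rows:
        buf.write(f"{r['region']},{r['pixel_count']},{r['area_km2']:g}\n")
    if unassigned["pixel_count"]:
        buf.write(
            f"{UNASSIGNED},{unassigned['pixel_count']},{unassigned['area_km2']:g}\n"
        )
    buf.write(f"TOTAL,{total_px},{total_km2:g}\n")

    mask_px = int(np.sum(result.final.values == 1))
    consistent = "OK" if mask_px == total_px else "MISMATCH"
    n_nonzero = sum(1 for r in rows if r["pixel_count"] > 0)
    text = (
        f"Final priority area: {total_km2:g} km2 ({total_px} pixels)\n"
        f"{n_nonzero} of {len(rows)} regions selected\n"
        f"Tabulation vs final mask: {consistent}\n"
    )
    return buf.getvalue(), text
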