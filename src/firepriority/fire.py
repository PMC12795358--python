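"""Fire history: annual burn-date composites, multi-year frequency, criteria.

Input is a series of monthly burn-date rasters in the MCD64A1 convention:
per pixel, 0 = unburned that month, 1..366 = day of year of the most
recent detected burn, negative codes = water/unmapped. Annual compositing
takes the maximum positive burn date (the latest fire of the year);
frequency counts the number of years whose composite is positive.

A pixel that burns twice within one calendar year still counts as one
burn *year* — frequency is defined over annual composites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import MASK_NODATA, Raster, pixel_area_km2, require_aligned

__all__ = [
    "BurnDateRaster",
    "FireFrequencyRaster",
    "annual_composite",
    "burn_frequency",
    "burned_any_mask",
    "repetitive_mask",
    "area_by_frequency",
]

#: nodata sentinel for integer burn-date / frequency rasters
INT_NODATA = -9999


@dataclass
class BurnDateRaster(Raster):
    """Annual composite: 0 = unburned, 1..366 = day of year of latest burn."""

    year: int = 0


@dataclass
class FireFrequencyRaster(Raster):
    """Per-pixel count of burn years over ``year_range`` (inclusive)."""

    year_range: tuple[int, int] = (0, 0)


def annual_composite(monthly: list[Raster], year: int) -> BurnDateRaster:
    """Collapse one year of monthly burn-date rasters to the latest burn.

    Per pixel: maximum positive burn date across the months, 0 if no month
    recorded a burn. Non-positive special codes (water/unmapped fill) are
    treated as "no burn observed"; a pixel is nodata only where *all*
    months are nodata.
    """
    if not monthly:
        raise ValueError("annual_composite: need at least one monthly raster")
    require_aligned(*monthly, what="annual_composite")

    stack = np.stack([np.asarray(m.values) for m in monthly]).astype(np.int32)
    invalid = np.stack([m.nodata_mask() for m in monthly])
    # special codes <= 0 carry no burn information
    stack = np.where(invalid | (stack <= 0), 0, stack)
    comp = stack.max(axis=0)
    comp[invalid.all(axis=0)] = INT_NODATA
    return BurnDateRaster(
        monthly[0].grid, comp, nodata=INT_NODATA, band="burn day-of-year", year=year
    )


def burn_frequency(composites: list[BurnDateRaster]) -> FireFrequencyRaster:
    """Count, per pixel, the years whose annual composite is positive.

    Requires one composite per distinct year; the result is independent of
    the order in which years are supplied. A pixel nodata in some years is
    counted over the remaining years; it is nodata only if nodata in all.
    """
    if not composites:
        raise ValueError("burn_frequency: need at least one composite")
    years = [c.year for c in composites]
    if len(set(years)) != len(years):
        raise ValueError(f"burn_frequency: duplicate years in {sorted(years)}")
    require_aligned(*composites, what="burn_frequency")

    burned = np.stack([np.asarray(c.values) > 0 for c in composites])
    invalid = np.stack([c.nodata_mask() for c in composites])
    freq = np.sum(burned & ~invalid, axis=0).astype(np.int32)
    freq[invalid.all(axis=0)] = INT_NODATA
    return FireFrequencyRaster(
        composites[0].grid,
        freq,
        nodata=INT_NODATA,
        band="burn-year count",
        year_range=(min(years), max(years)),
    )


def _freq_threshold_mask(freq: FireFrequencyRaster, k: int, label: str) -> Raster:
    vals = np.asarray(freq.values)
    out = (vals >= k).astype(np.uint8)
    out[freq.nodata_mask()] = MASK_NODATA
    return Raster(freq.grid, out, nodata=MASK_NODATA, band=label)


def burned_any_mask(freq: FireFrequencyRaster) -> Raster:
    """Boolean mask of pixels burned in at least one year."""
    return _freq_threshold_mask(freq, 1, "burned_any")


def repetitive_mask(freq: FireFrequencyRaster, threshold: int = 2) -> Raster:
    """The repetitive-fire criterion: burned in ``threshold`` (default 2,
    i.e. "twice or more") distinct years of the record."""
    return _freq_threshold_mask(freq, threshold, "repetitive_fire")


def area_by_frequency(freq: FireFrequencyRaster) -> list[dict]:
    """Tabulate pixel count and km² per burn-frequency class (1..max).

    Returns rows ``{"frequency": k, "pixel_count": n, "area_km2": a}``;
    class areas sum to the burned-at-least-once area by construction.
    """
    px = pixel_area_km2(freq.grid)
    vals = np.asarray(freq.values)[~freq.nodata_mask()]
    top = int(vals.max()) if vals.size else 0
    rows = []
    for k in range(1, top + 1):
        n = int(np.sum(vals == k))
        rows.append({"frequency": k, "pixel_count": n, "area_km2": n * px})
    return rows
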