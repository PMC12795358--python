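"""Burn-date compositing and fire frequency on a toy burn record.

Builds three years of monthly burn-date rasters for a 5x5 grid of 500 m
pixels, composites each year to the latest burn, counts burn years per
pixel, and reports the burned and repeatedly-burned areas.
"""

import numpy as np

from firepriority import (
    GridSpec,
    Raster,
    annual_composite,
    burn_frequency,
    burned_any_mask,
    mask_area_km2,
    repetitive_mask,
)
from firepriority.fire import INT_NODATA

grid = GridSpec("EPSG:2100", 300000.0, 4500000.0, 500.0, 500.0, 5, 5)

# pixel (0,0): burns twice in 2001 (Feb day 45, Sep day 250) and again in
# 2003 -> 2 burn *years*; pixel (2,2): burns once in 2002 -> 1 burn year
events = {
    2001: [((0, 0), 45), ((0, 0), 250)],
    2002: [((2, 2), 180)],
    2003: [((0, 0), 210)],
}

composites = []
for year, burns in events.items():
    monthly = []
    for month in range(1, 13):
        vals = np.zeros(grid.shape, dtype=np.int16)
        for (r, c), doy in burns:
            # place each event in the raster of its calendar month
            month_of = int(np.searchsorted(
                [32, 60, 91, 121, 152, 182, 213, 244, 274, 305, 335, 366], doy,
                side="right")) + 1
            if month_of == month:
                vals[r, c] = doy
        monthly.append(Raster(grid, vals, nodata=INT_NODATA))
    comp = annual_composite(monthly, year)
    composites.append(comp)
    print(f"{year}: latest burn at (0,0) = day {comp.values[0, 0]}")

freq = burn_frequency(composites)
print(f"\nburn-year count at (0,0): {freq.values[0, 0]}  (two burns in 2001 "
      "collapse to one burn year)")
print(f"burn-year count at (2,2): {freq.values[2, 2]}")
print(f"burned at least once: {mask_area_km2(burned_any_mask(freq)):g} km2")
print(f"burned repeatedly (>=2 years): {mask_area_km2(repetitive_mask(freq)):g} km2")
# Expected: (0,0) has 2 burn years and (2,2) one, so 0.5 km2 burned
# (2 pixels x 0.25 km2) of which 0.25 km2 repeatedly.
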