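"""Horn slope from a synthetic DEM and the steep-slope criterion at 500 m.

Builds a 30 m DEM that is a gentle 10-degree ramp with one 25-degree
patch, computes slope with Horn's 3x3 kernel, and shows the two-step
harmonization onto the 500 m analysis grid: binarize at >15 degrees,
area-weighted average, re-binarize at the 0.5 majority fraction.
"""

import math

import numpy as np

from firepriority import GridSpec, Raster, compute_slope, steep_mask

fine = GridSpec("EPSG:2100", 0.0, 3000.0, 30.0, 30.0, 100, 100)
coarse = GridSpec("EPSG:2100", 0.0, 3000.0, 500.0, 500.0, 6, 6)

# base ramp at 10 degrees; columns 34..66 (~1 coarse cell + margin) at 25
xs, _ = fine.cell_centers()
z = math.tan(math.radians(10)) * xs
steeper = math.tan(math.radians(25))
z[:, 34:67] = z[:, 34:35] + steeper * (xs[:, 34:67] - xs[:, 34:35])

slope = compute_slope(Raster(fine, z, band="elevation m"))
print(f"slope at a background pixel: {slope.values[50, 10]:.3f} deg")
print(f"slope inside the steep patch: {slope.values[50, 50]:.3f} deg")

mask = steep_mask(slope, coarse, threshold_deg=15.0, fraction_threshold=0.5)
print("\nsteep-slope criterion on the 6x6 analysis grid (1 = steeper than 15):")
print(mask.values)
# Only the two coarse columns whose footprints are mostly covered by the
# 25-degree patch pass the majority rule; the 10-degree background never does.
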