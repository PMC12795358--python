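# Methods

## Problem and model

The package ranks landscape pixels by restoration urgency after
wildfire using three boolean criteria drawn from practitioner
priorities: recurrent burning, erosion-prone steep terrain, and
protected-area status. The combination is deliberately unweighted — a
pixel either meets a criterion or it does not — which keeps the method
auditable for agencies without multi-criteria-decision tooling. The
two-tier output (preselection at ≥ 2 criteria, final at 3) mirrors how
such overlays are screened in practice: the looser map for situational
awareness, the strict intersection for targeting.

All computation happens on a single, explicitly declared analysis grid
in a projected meter-unit CRS. This is a conscious departure from
GIS-environment conventions where the raster calculator silently
resamples mixed-resolution inputs ("maximum of inputs" cell size):
implicit environment-driven resampling is not reproducible across
installations, so here the 30 m slope product must be brought onto the
analysis grid by an explicit, documented aggregation step, and every
overlay refuses unaligned inputs (same CRS, same cell size, origins
offset by integer cell multiples within 1e-6 of a cell).

## Stages

**Fire history.** Monthly burn-date rasters use the burned-area product
convention: 0 unburned, 1–366 day of year of the most recent burn,
negative codes for water/unmapped. Codes ≤ 0 are treated as "no burn
observed" rather than nodata-poisoning, so fill never counts as fire;
a pixel is nodata only where every month is nodata. The annual
composite is the maximum positive burn date (the latest fire of the
year); frequency counts years with a positive composite, so two burns
in one calendar year count once. The default window is 2001–2023
inclusive (23 years; the partial first product year is excluded). The
repetitive criterion is frequency ≥ 2 ("twice or more"); the threshold
is configurable (`repetitive_threshold`).

**Terrain.** Slope uses Horn's 3×3 weighted finite differences, the
algorithm documented for the slope tools of mainstream GIS software and
exact on planes (the property tests exploit this: planar DEMs must
match `arctan |∇z|` to 1e-6°). Borders are computed after edge
replication rather than emitting a nodata ring — coastal pixels remain
usable, which matters for island-heavy coastlines; any nodata inside
the 3×3 window poisons the center pixel. The criterion threshold is
strictly `> 15°`, the lower bound reported for sharply increased
landslide frequency on Greek terrain; pixels at exactly 15° are
excluded.

**Resolution harmonization.** The default order is: binarize slope at
30 m, aggregate the 0/1 mask to 500 m by area-weighted averaging
(interval-overlap weights, exact for the non-integer 500/30 ratio),
re-binarize at fraction ≥ 0.5. Whether "spatial averaging" in
tool-based workflows is applied to the slope raster or to the
reclassified mask is genuinely ambiguous; averaging the binary mask
keeps the criterion boolean and makes the 0.5 majority rule explicit,
so it is the default, with `slope_order: average_then_threshold` and
`steep_fraction_threshold` exposed for sensitivity runs. The two orders
differ on bimodal cells (e.g. 40 % of sub-pixels at 40°: mean slope 16°
passes the averaged-slope rule but fails the 0.4 < 0.5 majority); the
test suite pins one such separating case.

**Protected areas.** Polygons are repaired (`make_valid`, keeping the
polygonal part), clipped to the land boundary so marine components
never contribute terrestrial area, and kept as individual records —
rasterization is a boolean union, so overlapping designations cannot
double-count. The pixel-inclusion rule is the center-point test (the
default of feature-to-raster tools), not all-touched, which avoids
inflating protected area; rasterized area converges to polygon area as
the cell size shrinks. No designation or IUCN-category filtering is
applied by default.

**Overlay and tabulation.** The criteria count treats nodata in one
mask as "criterion not met" for that pixel instead of poisoning it —
national burned-area maps are partially unmapped along coasts, and a
pixel with two solid criteria should not vanish because the third is
unmapped there; only pixels nodata in all three masks are nodata.
Regional tabulation assigns each selected pixel center to the first
containing region in the stable input order (boundary-inclusive test),
making the assignment a partition: regional counts plus the
`_unassigned` remainder always sum to the mask total, and every km²
equals count × cell area exactly. Area is projected cell area
(`cell_x · cell_y / 10⁶`), matching pixel-count accounting on an
equal-area-suitable national projection; geographic (degree) grids are
rejected with instructions to reproject, and no geodesic correction is
attempted.

## Synthetic scenarios and what they show

The generator emulates the input stack at desk scale: a 60×60 analysis
grid at 500 m with a nested 1000×1000 grid at 30 m sharing the origin
(so aggregation is exercised without reprojection), 23 years of monthly
burn rasters, a DEM, protected rectangles and a rectangular region
partition. Fire is Bernoulli per pixel-year with a base probability of
0.05 — of the order of the burned-area fraction observed over a
two-decade Mediterranean record — modulated in logit space by a
Gaussian-smoothed noise field (correlation length 3 cells) so burns
cluster spatially as satellite burned-area maps do; the logit form
preserves the degenerate rates 0 and 1 exactly. One RNG stream per
scenario is consumed in a fixed order (per-year probability noise, burn
draws, day-of-year draws), so scenarios are bit-reproducible and vector
specs never perturb fire realizations.

Ground truth is planted constructively: "planted" pixels are forced to
burn in two distinct years, sit under a 25° ramp patch, and be covered
by a protected rectangle; decoy pixels get exactly 0, 1 or 2 criteria,
with random fire suppressed at any control pixel that must not meet the
fire criterion. Steep patches cover their analysis cell plus a
two-fine-cell margin, so edge artifacts from the piecewise DEM fall
well below the 0.5 majority in neighboring cells; protected rectangles
coincide with cell footprints, so the center rule selects exactly the
intended cells. Consequently the steep∧protected intersection exists
only at control pixels, and a correct pipeline's final mask equals the
planted set *regardless of the random background* — background pixels
can meet at most the fire criterion. Passing truth recovery therefore
certifies the overlay logic and criterion wiring, not performance on
real data: the generator does not emulate sinusoidal satellite
projection geometry, burn-severity structure, realistic fire spread, or
real DEM roughness.

## Numerical and interface choices

- Nodata: NaN for real rasters, −9999 for integer rasters, 255 for
  8-bit masks; operations propagate nodata rather than reading it as 0
  (the single documented exception is the criteria count above).
- Aggregation conserves the global mean of nodata-free rasters to
  1e-9 relative tolerance (tested against a brute-force double loop).
- GeoTIFF I/O is implemented directly on `tifffile` using the standard
  georeferencing tags (pixel scale, tiepoint, GeoKey directory with the
  EPSG code, GDAL nodata), readable by GDAL-based tools; vectors are
  GeoJSON with an explicit CRS member. The pipeline never reprojects:
  inputs must arrive in the analysis CRS, and validation fails loudly
  otherwise.
- The CLI is a thin wrapper over the library (`validate`, `run`,
  `make-scenario`, `tabulate`, `focus`); exit codes 0 / 2 / 3 for
  success / validation failure / stage failure. A failing stage removes
  partial outputs so a run directory is either complete or absent.
- Scenario sizes in tests and the acceptance script (60×60 at 500 m,
  1000×1000 at 30 m, 23 years) were chosen as the smallest geometry
  that still exercises non-integer-ratio aggregation, multi-region
  tabulation and a two-decade record.

## Known limitations

- No reprojection, no geodesic areas: results are only as good as the
  chosen national projection; runs in different CRSs are comparable
  only through the CRS recorded in the run log.
- Shapefile input is not supported; convert to GeoJSON upstream.
- Burn severity, fire-return intervals within a year, and burn-date
  uncertainty are out of scope; the composite's date value is preserved
  but unused by the criteria.
- The published national figures bundled for consistency checks are
  dataset-version-dependent; the package checks their internal
  arithmetic, not their reproduction from source data.
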