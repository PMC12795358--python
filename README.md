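# firepriority

A reproducible raster pipeline for prioritizing areas for post-fire
vegetation restoration, written for restoration planners, forest
services and researchers working with national-scale burned-area
records. It implements a three-criterion boolean overlay:

1. **Repetitive fire** — the pixel burned in ≥ 2 distinct years of a
   multi-year monthly burn-date record (MCD64A1-style "BurnDate"
   rasters, 500 m);
2. **Steep slope** — terrain slope strictly above 15°, derived from a
   30 m DEM with Horn's 3×3 method and harmonized to the analysis grid;
3. **Protected area** — the pixel center falls inside a terrestrial
   protected-area polygon (WDPA-style inventory).

Pixels meeting at least two criteria form the **preselection** map;
pixels meeting all three form the **final priority** map, whose area is
tabulated per administrative region.

## Method

All layers live on one pre-declared projected analysis grid (cell size
`c`, here 500 m, pixel area `c²/10⁶ = 0.25 km²`). Per pixel `i`:

- annual composite: `B_y(i) = max{ d > 0 : d a burn date in year y }`, else 0
- fire frequency: `F(i) = #{ y : B_y(i) > 0 }`; criterion `M_fire = [F ≥ 2]`
- slope: `S = arctan √((∂z/∂x)² + (∂z/∂y)²)` with Horn's weighted
  differences on the 30 m DEM; the binary map `[S > 15°]` is aggregated
  to 500 m by area-weighted averaging and re-binarized at fraction ≥ 0.5
  to give `M_slope`
- protection: `M_prot(i) = [center(i) ∈ ⋃ protected polygons]` after
  clipping polygons to the land boundary
- count `K = M_fire + M_slope + M_prot`; preselection `[K ≥ 2]`; final
  `[K = 3]`; every reported area is `(pixel count) × c²/10⁶`, so all
  areas are integer multiples of the cell area.

In the published Greek application of this workflow (2001–2023), the
final map covered 77.25 km² (309 pixels of 0.25 km²) across 12 of the 14
regions; those reference figures ship in `firepriority.reference` and
are used for internal-consistency checks only — reproducing the
national maps requires the multi-gigabyte MODIS/Copernicus/WDPA inputs,
which this package deliberately does not bundle.

## Worked example

`examples/full_pipeline.py` generates a synthetic scenario — 23 years of
monthly burn rasters on a 60×60 grid at 500 m, a nested 30 m DEM with
steep patches, protected and region polygons, plus pixels planted to
satisfy all three criteria and decoys satisfying exactly 0, 1 or 2 —
then runs the pipeline:

```
planted priority pixels: [(10, 10), (40, 40)]
final mask pixels:       [(10, 10), (40, 40)]
truth recovered exactly: True
final priority area: 0.5 km2

regional tabulation (pixel counts x 0.25 km2):
    region-0-0:  1 px, 0.25 km2
    region-0-1:  0 px, 0 km2
    region-1-0:  0 px, 0 km2
    region-1-1:  1 px, 0.25 km2
   _unassigned:  0 px, 0 km2
```

The final mask recovers exactly the planted ground truth: two-criteria
decoys reach preselection but not the final map, and random background
fires can meet at most the fire criterion. `examples/fire_frequency.py`
and `examples/slope_criterion.py` walk the fire-history and terrain
stages individually.

The same pipeline is scriptable from the shell:

```sh
firepriority make-scenario scen/ --seed 7
firepriority run --burn-dir scen/burn --dem scen/dem.tif \
    --protected scen/protected.geojson --regions scen/regions.geojson \
    --land scen/land.geojson --out-dir out/
firepriority tabulate out/final_priority.tif scen/regions.geojson
```

`run` writes `fire_frequency.tif`, the three criterion masks,
`criteria_count.tif`, `preselection.tif`, `final_priority.tif`,
`region_table.csv`, `area_by_frequency.csv` and a `run_log.json` with
the config echo, input checksums and the per-stage area chain. Two runs
with the same inputs and config are byte-identical.

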