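"""Published reference figures for the Greek national prioritization run.

The national analysis combined MCD64A1 burned-area data for 2001–2023,
Copernicus 30 m elevation, and WDPA protected-area polygons on a 500 m
analysis grid. Reproducing those national maps needs multi-gigabyte,
version-pinned downloads, so the package does not ship them; what it does
carry are the *reported* summary figures, used for internal-consistency
checks (the arithmetic identities that must hold between the printed
numbers) and as a worked reference in the docs.

All areas in km² on the 500 m grid, where one pixel is 0.25 km².
"""

from __future__ import annotations

__all__ = [
    "REGIONAL_PRIORITY_AREAS_KM2",
    "TOTAL_PRIORITY_AREA_KM2",
    "BURNED_AT_LEAST_ONCE_KM2",
    "BURNED_REPEATEDLY_KM2",
    "STEEP_SLOPE_KM2",
    "PROTECTED_LAND_KM2",
    "N_PROTECTED_AREAS",
    "YEAR_RANGE",
    "CELL_AREA_KM2",
]

#: analysis window (inclusive): 23 fire years
YEAR_RANGE = (2001, 2023)

#: area of one 500 m × 500 m analysis pixel
CELL_AREA_KM2 = 0.25

#: reported area selected for restoration prioritization, by region;
#: all 14 Greek regions (incl. the autonomous Mount Athos), zeros where
#: no area was selected
REGIONAL_PRIORITY_AREAS_KM2: dict[str, float] = {
    "Peloponnese": 22.75,
    "Central Greece": 18.5,
    "East Macedonia and Thrace": 9.25,
    "West Greece": 7.0,
    "North Aegean": 5.25,
    "Attica": 4.75,
    "South Aegean": 2.75,
    "Thessaly": 2.25,
    "Epirus": 1.5,
    "Crete": 1.5,
    "Ionian Islands": 1.25,
    "Central Macedonia": 0.5,
    "West Macedonia": 0.0,
    "Mount Athos": 0.0,
}

#: reported national total of the final priority map
TOTAL_PRIORITY_AREA_KM2 = 77.25

#: area burned in at least one year of the record
BURNED_AT_LEAST_ONCE_KM2 = 15207.0

#: area burned in two or more years ("repetitively")
BURNED_REPEATEDLY_KM2 = 2598.0

#: area with slope strictly above 15 degrees
STEEP_SLOPE_KM2 = 42169.0

#: terrestrial protected-area coverage
PROTECTED_LAND_KM2 = 46224.0

#: protected-area records (terrestrial and marine) in the inventory
N_PROTECTED_AREAS = 1289
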