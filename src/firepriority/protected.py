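"""Protected-area polygons: loading, terrestrial clipping, rasterization.

Protected-area inventories (WDPA-style) mix terrestrial and marine
designations; all three prioritization criteria are terrestrial, so
polygons are clipped to a land boundary before rasterization. Overlapping
designations are kept as separate records — the raster criterion is their
boolean union, so double-designation never double-counts.

Rasterization uses the pixel-center rule (a pixel is protected iff its
center point falls inside a polygon), matching the default of standard
feature-to-raster GIS tools and avoiding systematic area inflation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

from .grid import MASK_NODATA, AlignmentError, GridSpec, Raster
from .io import read_geojson

__all__ = ["ProtectedArea", "ProtectedAreaSet", "load_protected", "rasterize_protected"]

_POLY_TYPES = ("Polygon", "MultiPolygon")


@dataclass
class ProtectedArea:
    geometry: BaseGeometry
    name: str = ""
    designation: str = ""
    iucn_category: str = "Not Reported"
    marine_flag: bool = False


@dataclass
class ProtectedAreaSet:
    """Repaired, land-clipped protected-area polygons in the analysis CRS."""

    areas: list[ProtectedArea] = field(default_factory=list)
    crs: str | None = None

    def __len__(self) -> int:
        return len(self.areas)

    def geometries(self) -> list[BaseGeometry]:
        return [a.geometry for a in self.areas]

    def inventory(self, pixel_km2: float | None = None) -> list[dict[str, Any]]:
        """Attribute table with clipped polygon areas in km²."""
        return [
            {
                "name": a.name,
                "designation": a.designation,
                "iucn_category": a.iucn_category,
                "clipped_area_km2": a.geometry.area / 1e6,
            }
            for a in self.areas
        ]


def _only_polygonal(geom: BaseGeometry) -> BaseGeometry:
    """Keep the polygonal part of a (possibly mixed) repaired geometry."""
    if geom.geom_type in _POLY_TYPES:
        return geom
    if geom.geom_type == "GeometryCollection":
        polys = [g for g in geom.geoms if g.geom_type in _POLY_TYPES]
        return shapely.union_all(polys) if polys else shapely.Polygon()
    return shapely.Polygon()


def load_protected(
    vector_path: str | os.PathLike,
    land_boundary: BaseGeometry | None = None,
) -> ProtectedAreaSet:
    """Load protected-area polygons from GeoJSON, repair invalid
    geometries, and clip to the terrestrial extent.

    Polygons wholly at sea (empty intersection with the land boundary)
    are dropped; coastal polygons keep their land part only. Attributes
    ``name`` / ``designation`` / ``iucn_category`` (also accepted in WDPA
    capitalization ``NAME`` / ``DESIG`` / ``IUCN_CAT``) are preserved.

    Raises
    ------
    ValueError
        if the file has no polygon features or no CRS record.
    """
    geoms, props, crs = read_geojson(vector_path)
    if crs is None:
        raise ValueError(f"{vector_path}: GeoJSON lacks a CRS record; "
                         "inputs must be pre-projected to the analysis CRS")
    areas: list[ProtectedArea] = []
    for geom, p in zip(geoms, props):
        if geom.geom_type not in _POLY_TYPES:
            continue
        if not geom.is_valid:
            geom = _only_polygonal(make_valid(geom))
        if land_boundary is not None:
            geom = _only_polygonal(geom.intersection(land_boundary))
        if geom.is_empty:
            continue
        areas.append(
            ProtectedArea(
                geometry=geom,
                name=str(p.get("name", p.get("NAME", ""))),
                designation=str(p.get("designation", p.get("DESIG", ""))),
                iucn_category=str(
                    p.get("iucn_category", p.get("IUCN_CAT", "Not Reported"))
                ),
                marine_flag=bool(p.get("marine_flag", p.get("MARINE", False))),
            )
        )
    if not areas:
        raise ValueError(f"{vector_path}: no terrestrial polygon features")
    return ProtectedAreaSet(areas=areas, crs=crs)


def rasterize_mask(
    geometries: list[BaseGeometry], grid: GridSpec, label: str
) -> Raster:
    """Boolean-union rasterization of polygons by the pixel-center rule."""
    out = np.zeros(grid.shape, dtype=np.uint8)
    if geometries:
        union = shapely.union_all([g for g in geometries if not g.is_empty])
        if not union.is_empty:
            xs, ys = grid.cell_centers()
            out = shapely.contains_xy(union, xs.ravel(), ys.ravel()).reshape(
                grid.shape
            ).astype(np.uint8)
    return Raster(grid, out, nodata=MASK_NODATA, band=label)


def rasterize_protected(pas: ProtectedAreaSet, grid: GridSpec) -> Raster:
    """Protected-area criterion mask: pixel = 1 iff its center lies inside
    any protected polygon.

    Raises
    ------
    AlignmentError
        if the polygon CRS is recorded and differs from the grid CRS.
    """
    if pas.crs is not None and pas.crs.strip().upper() != grid.crs.strip().upper():
        raise AlignmentError(
            f"rasterize_protected: polygons in {pas.crs!r}, grid in {grid.crs!r}"
        )
    return rasterize_mask(pas.geometries(), grid, "protected_area")
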