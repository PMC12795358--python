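"""GeoTIFF and GeoJSON I/O.

Rasters are read and written as single-band GeoTIFFs: the grid geometry
travels in the standard ModelPixelScale / ModelTiepoint tags, the CRS in
a minimal GeoKey directory (EPSG code) plus the GeoAsciiParams tag, and
the nodata sentinel in the GDAL_NODATA ASCII tag — the tag set GDAL and
QGIS read. Boolean masks are written as 8-bit with {0, 1, 255=nodata}.

Vector data (protected areas, regions, land boundary) is GeoJSON; the
CRS identifier is carried in the legacy ``crs.properties.name`` member so
projected, meter-unit coordinates survive a round trip.
"""

from __future__ import annotations

import json
import math
import os
from typing import Any

import numpy as np
import shapely
import tifffile
from shapely.geometry import mapping, shape

from .grid import GridSpec, Raster

__all__ = [
    "read_geotiff",
    "write_geotiff",
    "read_geojson",
    "write_geojson",
]

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GEO_ASCII_PARAMS = 34737
_TAG_GDAL_NODATA = 42113


def _geokeys(crs: str) -> list[int]:
    """Minimal GeoKey directory: projected model + EPSG code if parseable."""
    keys = []
    epsg = None
    c = crs.strip().upper()
    if c.startswith("EPSG:"):
        try:
            epsg = int(c.split(":", 1)[1])
        except ValueError:
            epsg = None
    # GTModelTypeGeoKey (1024): 1 = projected, 2 = geographic
    model = 2 if c in ("EPSG:4326", "OGC:CRS84") else 1
    keys.append((1024, 0, 1, model))
    if epsg is not None:
        key_id = 2048 if model == 2 else 3072  # Geographic vs ProjectedCSType
        keys.append((key_id, 0, 1, epsg))
    header = [1, 1, 0, len(keys)]
    return header + [v for k in keys for v in k]


def write_geotiff(path: str | os.PathLike, raster: Raster) -> None:
    """Write a single-band GeoTIFF carrying grid, CRS and nodata tags."""
    g = raster.grid
    values = np.asarray(raster.values)
    ascii_params = g.crs + "|"
    nodata = raster.nodata
    nodata_str = "nan" if (
        isinstance(nodata, float) and math.isnan(nodata)
    ) else ("" if nodata is None else repr(nodata))

    geokeys = _geokeys(g.crs)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (g.cell_size_x, g.cell_size_y, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.origin_x, g.origin_y, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
        (_TAG_GEO_ASCII_PARAMS, "s", 0, ascii_params),
    ]
    if nodata_str:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, nodata_str))
    tifffile.imwrite(path, values, extratags=extratags)


def _parse_nodata(s: str, dtype: np.dtype) -> float | int | None:
    s = s.strip().rstrip("\x00").strip()
    if not s:
        return None
    if s.lower() == "nan":
        return float("nan")
    v = float(s)
    if np.issubdtype(dtype, np.integer):
        return int(v)
    return v


def read_geotiff(path: str | os.PathLike, band: str = "") -> Raster:
    """Read a single-band GeoTIFF written by :func:`write_geotiff` (or any
    GeoTIFF carrying pixel-scale and tiepoint tags)."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = {t.code: t.value for t in page.tags.values()}

    if values.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster")
    if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
        raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")

    sx, sy = tags[_TAG_MODEL_PIXEL_SCALE][:2]
    tp = tags[_TAG_MODEL_TIEPOINT]
    # tiepoint maps raster (i, j) -> model (x, y); we require corner anchoring
    ox = tp[3] - tp[0] * sx
    oy = tp[4] + tp[1] * sy

    crs = ""
    if _TAG_GEO_ASCII_PARAMS in tags:
        crs = str(tags[_TAG_GEO_ASCII_PARAMS]).split("|")[0].rstrip("\x00")
    if not crs and _TAG_GEO_KEY_DIRECTORY in tags:
        d = list(tags[_TAG_GEO_KEY_DIRECTORY])
        n = d[3]
        for k in range(n):
            key_id, _, _, val = d[4 + 4 * k : 8 + 4 * k]
            if key_id in (2048, 3072):
                crs = f"EPSG:{val}"
    if not crs:
        raise ValueError(f"{path}: no CRS recorded in GeoTIFF keys")

    nodata = None
    if _TAG_GDAL_NODATA in tags:
        nodata = _parse_nodata(str(tags[_TAG_GDAL_NODATA]), values.dtype)

    grid = GridSpec(
        crs=crs,
        origin_x=float(ox),
        origin_y=float(oy),
        cell_size_x=float(sx),
        cell_size_y=float(sy),
        n_rows=values.shape[0],
        n_cols=values.shape[1],
    )
    return Raster(grid, values, nodata=nodata, band=band)


# --- GeoJSON ----------------------------------------------------------------


def write_geojson(
    path: str | os.PathLike,
    geometries: list[shapely.Geometry],
    properties: list[dict[str, Any]] | None = None,
    crs: str | None = None,
) -> None:
    """Write geometries (+ per-feature properties) as a FeatureCollection."""
    props = properties or [{} for _ in geometries]
    if len(props) != len(geometries):
        raise ValueError("write_geojson: properties/geometries length mismatch")
    fc: dict[str, Any] = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": p}
            for geom, p in zip(geometries, props)
        ],
    }
    if crs:
        fc["crs"] = {"type": "name", "properties": {"name": crs}}
    with open(path, "w") as fh:
        json.dump(fc, fh)


def read_geojson(
    path: str | os.PathLike,
) -> tuple[list[shapely.Geometry], list[dict[str, Any]], str | None]:
    """Read a GeoJSON FeatureCollection.

    Returns (geometries, properties, crs identifier or None).
    """
    with open(path) as fh:
        fc = json.load(fh)
    if fc.get("type") == "Feature":
        fc = {"type": "FeatureCollection", "features": [fc]}
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    geoms, props = [], []
    for feat in fc.get("features", []):
        geoms.append(shape(feat["geometry"]))
        props.append(feat.get("properties") or {})
    crs = None
    if isinstance(fc.get("crs"), dict):
        crs = fc["crs"].get("properties", {}).get("name")
    return geoms, props, crs
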