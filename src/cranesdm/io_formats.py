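"""Readers and writers for the pipeline's external artifacts.

Rasters are GeoTIFFs with an axis-aligned, square-cell geotransform encoded
in the standard ModelPixelScale / ModelTiepoint tags and nodata in the
GDAL_NODATA ASCII tag.  Point tables are plain CSV with planar ``x, y``
columns; polygon sets are GeoJSON FeatureCollections; run configuration is
YAML.  Everything round-trips: ``read(write(obj)) == obj``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape

from .grid import PointTable, PolygonSet, RasterGrid, check_aligned

__all__ = [
    "read_raster",
    "write_raster",
    "read_points",
    "write_points",
    "read_polygons",
    "write_polygons",
    "read_config",
    "write_config",
]

# GeoTIFF / GDAL tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_MODEL_TRANSFORMATION = 34264
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113


def write_raster(grid: RasterGrid | Sequence[RasterGrid], path) -> Path:
    """Write one grid (single band) or several aligned grids (multi-band).

    The array dtype is preserved, so integer data round-trips bit-for-bit
    and floats round-trip exactly in their own precision.  Layer names go
    into the ImageDescription tag as JSON.
    """
    path = Path(path)
    grids = [grid] if isinstance(grid, RasterGrid) else list(grid)
    if not grids:
        raise ValueError("no grids to write")
    check_aligned(*grids)
    g0 = grids[0]
    nodatas = {g.nodata for g in grids}
    if len(nodatas) > 1:
        raise ValueError(f"grids disagree on nodata: {nodatas}")

    data = grids[0].values if len(grids) == 1 else np.stack([g.values for g in grids])
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (float(g0.cell_size), float(g0.cell_size), 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(g0.origin_x), float(g0.origin_y), 0.0)),
    ]
    if g0.nodata is not None:
        extratags.append((_GDAL_NODATA, "s", 0, repr(g0.nodata)))
    description = json.dumps({"names": [g.name for g in grids]})
    tifffile.imwrite(
        path,
        data,
        extratags=extratags,
        description=description,
        photometric="minisblack",
        metadata=None,
    )
    return path


def read_raster(path) -> RasterGrid | list[RasterGrid]:
    """Read a GeoTIFF into RasterGrid(s); a list is returned for multi-band.

    Raises on rotated (non-axis-aligned) or non-square-cell geotransforms.
    A file without a CRS key directory is accepted with a warning; planar
    metre coordinates are assumed throughout.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        tags = page.tags
        if _MODEL_TRANSFORMATION in tags:
            m = np.asarray(tags[_MODEL_TRANSFORMATION].value, dtype=float).reshape(4, 4)
            if m[0, 1] != 0 or m[1, 0] != 0:
                raise ValueError(
                    f"non-axis-aligned raster: ModelTransformation has rotation terms "
                    f"({m[0, 1]}, {m[1, 0]})"
                )
            sx, sy = m[0, 0], -m[1, 1]
            origin_x, origin_y = m[0, 3], m[1, 3]
        elif _MODEL_PIXEL_SCALE in tags and _MODEL_TIEPOINT in tags:
            scale = tags[_MODEL_PIXEL_SCALE].value
            tie = tags[_MODEL_TIEPOINT].value
            sx, sy = float(scale[0]), float(scale[1])
            # tiepoint maps raster (i, j) to model (x, y); demand the corner
            i, j = float(tie[0]), float(tie[1])
            origin_x = float(tie[3]) - j * sx
            origin_y = float(tie[4]) + i * sy
        else:
            raise ValueError(f"{path}: no geotransform tags (not a GeoTIFF?)")
        if not np.isclose(sx, sy):
            raise ValueError(
                f"non-square cells: ModelPixelScale gives x-size {sx} but y-size {sy}"
            )
        if _GEO_KEY_DIRECTORY not in tags:
            warnings.warn(
                f"{path.name}: no CRS information; planar metre coordinates assumed",
                stacklevel=2,
            )
        nodata = None
        if _GDAL_NODATA in tags:
            raw = tags[_GDAL_NODATA].value
            nodata = float(raw) if ("." in str(raw) or "e" in str(raw)) else int(raw)
        names: list[str] = []
        desc = page.description or ""
        if desc:
            try:
                names = json.loads(desc).get("names", [])
            except (json.JSONDecodeError, AttributeError):
                names = []
        data = tif.asarray()

    def _mk(values: np.ndarray, name: str) -> RasterGrid:
        return RasterGrid(
            values=values,
            origin_x=origin_x,
            origin_y=origin_y,
            cell_size=sx,
            nodata=nodata,
            name=name,
        )

    if data.ndim == 2:
        return _mk(data, names[0] if names else path.stem)
    bands = [
        _mk(data[b], names[b] if b < len(names) else f"{path.stem}_band{b + 1}")
        for b in range(data.shape[0])
    ]
    return bands


def write_points(points: PointTable, path) -> Path:
    """Write a point table to CSV (id, x, y, role, then extra columns)."""
    path = Path(path)
    points.data.to_csv(path, index=False)
    return path


def read_points(path, role: str | None = None) -> PointTable:
    """Read a CSV of planar points; ids are assigned sequentially.

    The file must have numeric ``x`` and ``y`` columns.  ``role`` stamps
    every row; if omitted, a ``role`` column must be present in the file.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    for col in ("x", "y"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            rows = df.index[numeric.isna()].tolist()
            raise ValueError(
                f"{path}: non-numeric {col!r} coordinate in row(s) {rows[:10]}"
            )
        df[col] = numeric
    if role is not None:
        df["role"] = role
    elif "role" not in df.columns:
        raise ValueError(f"{path}: no 'role' column and no role argument given")
    df["id"] = np.arange(len(df), dtype=np.int64)
    ordered = ["id", "x", "y", "role"] + [
        c for c in df.columns if c not in ("id", "x", "y", "role")
    ]
    return PointTable(df[ordered])


def write_polygons(polys: PolygonSet, path) -> Path:
    """Write polygons as a GeoJSON FeatureCollection."""
    path = Path(path)
    features = [
        {
            "type": "Feature",
            "properties": {"label": polys.label, "index": i},
            "geometry": shapely_mapping(geom),
        }
        for i, geom in enumerate(polys.polygons)
    ]
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path


def read_polygons(path, label: str | None = None) -> PolygonSet:
    """Read a GeoJSON FeatureCollection of (Multi)Polygons."""
    path = Path(path)
    doc = json.loads(path.read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    geoms = []
    inferred = label
    for feat in doc.get("features", []):
        geoms.append(shapely_shape(feat["geometry"]))
        if inferred is None:
            inferred = (feat.get("properties") or {}).get("label")
    return PolygonSet(polygons=geoms, label=inferred or "")


def write_config(config: dict[str, Any], path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config, sort_keys=False))
    return path


def read_config(path) -> dict[str, Any]:
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return doc
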