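"""Core spatial containers: regular raster grids, point tables, polygon sets.

All coordinates are planar metres in a projected, axis-aligned system.
Rasters follow the north-up GeoTIFF convention: row index increases as y
decreases, the grid origin is the *top-left corner* of cell (0, 0), and
cells are square.  Point-in-cell assignment is half-open — a point on the
left/top edge of a cell belongs to that cell — so every in-bounds point
maps to exactly one cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import shape as _shapely_shape
from shapely.geometry.base import BaseGeometry

__all__ = ["RasterGrid", "PointTable", "PolygonSet", "GridAlignmentError"]

#: reserved (non-covariate) column names in a PointTable frame
POINT_BASE_COLUMNS = ("id", "x", "y", "role", "rio", "flagged")

POINT_ROLES = frozenset({"presence", "pseudo_absence", "test"})


class GridAlignmentError(ValueError):
    """Raised when rasters that must share a grid do not."""


@dataclass
class RasterGrid:
    """A regular 2-D cell grid carrying one named layer.

    Parameters
    ----------
    values
        2-D array, shape (rows, cols).
    origin_x, origin_y
        Planar coordinates (metres) of the grid's top-left corner.
    cell_size
        Edge length of the square cells, metres; > 0.
    nodata
        Sentinel value marking missing cells, or None.
    name
        Layer label (e.g. ``"Altitude"``).
    """

    values: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float
    nodata: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"raster values must be 2-D, got shape {self.values.shape}")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("raster must have at least one row and one column")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid footprint."""
        s = self.cell_size
        return (
            self.origin_x,
            self.origin_y - self.rows * s,
            self.origin_x + self.cols * s,
            self.origin_y,
        )

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """Planar (x, y) of the centre(s) of cell(s) (row, col)."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y - (row + 0.5) * self.cell_size
        return x, y

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids (rows × cols) of all cell-centre coordinates."""
        rr, cc = np.meshgrid(np.arange(self.rows), np.arange(self.cols), indexing="ij")
        return self.cell_center(rr, cc)

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Cell index (row, col) containing point(s) (x, y), half-open rule.

        Out-of-bounds points get indices outside [0, rows) × [0, cols);
        callers use :meth:`in_bounds` or check ranges themselves.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(np.int64)
        row = np.floor((self.origin_y - y) / self.cell_size).astype(np.int64)
        return row, col

    def in_bounds(self, x, y) -> np.ndarray:
        row, col = self.index_of(x, y)
        return (row >= 0) & (row < self.rows) & (col >= 0) & (col < self.cols)

    # -- masking / derivation --------------------------------------------

    def nodata_mask(self) -> np.ndarray:
        """Boolean array, True where the cell is nodata."""
        if self.nodata is None:
            return np.zeros(self.shape, dtype=bool)
        if np.isnan(self.nodata) if isinstance(self.nodata, float) else False:
            return np.isnan(self.values)
        return self.values == self.nodata

    def with_values(self, values: np.ndarray, name: str | None = None,
                    nodata: float | None = None) -> "RasterGrid":
        """A new grid on the same geometry with different values."""
        return RasterGrid(
            values=np.asarray(values),
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            cell_size=self.cell_size,
            nodata=nodata,
            name=self.name if name is None else name,
        )

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.origin_x, other.origin_x)
            and np.isclose(self.origin_y, other.origin_y)
            and np.isclose(self.cell_size, other.cell_size)
        )


def check_aligned(*grids: RasterGrid) -> None:
    """Raise GridAlignmentError unless all grids share geometry and shape."""
    ref = grids[0]
    for g in grids[1:]:
        if not ref.aligned_with(g):
            raise GridAlignmentError(
                f"raster {g.name!r} (shape {g.shape}, origin "
                f"({g.origin_x}, {g.origin_y}), cell {g.cell_size}) is not aligned "
                f"with {ref.name!r} (shape {ref.shape}, origin "
                f"({ref.origin_x}, {ref.origin_y}), cell {ref.cell_size})"
            )


@dataclass
class PointTable:
    """Labelled planar points with optional extracted covariates and scores.

    Backed by a DataFrame with reserved columns ``id, x, y, role`` plus
    optional ``rio`` and ``flagged``; every other column is a covariate.
    Roles come from the closed set {presence, pseudo_absence, test}.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("id", "x", "y", "role"):
            if col not in df.columns:
                raise ValueError(f"PointTable frame missing required column {col!r}")
        bad = set(df["role"].unique()) - POINT_ROLES
        if bad:
            raise ValueError(f"unknown point roles: {sorted(bad)}")
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate point ids: {dupes[:5]}")

    @classmethod
    def from_xy(cls, x: Sequence[float], y: Sequence[float], role: str,
                start_id: int = 0) -> "PointTable":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if role not in POINT_ROLES:
            raise ValueError(f"role must be one of {sorted(POINT_ROLES)}, got {role!r}")
        df = pd.DataFrame({
            "id": np.arange(start_id, start_id + len(x), dtype=np.int64),
            "x": x,
            "y": y,
            "role": role,
        })
        return cls(df)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def x(self) -> np.ndarray:
        return self.data["x"].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.data["y"].to_numpy()

    @property
    def roles(self) -> pd.Series:
        return self.data["role"]

    @property
    def rio(self) -> np.ndarray:
        if "rio" not in self.data.columns:
            raise AttributeError("points have not been scored (no 'rio' column)")
        return self.data["rio"].to_numpy()

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in POINT_BASE_COLUMNS]

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data[self.covariate_names]

    @property
    def flagged(self) -> np.ndarray:
        if "flagged" in self.data.columns:
            return self.data["flagged"].to_numpy(dtype=bool)
        return np.zeros(len(self.data), dtype=bool)

    def with_columns(self, **cols) -> "PointTable":
        df = self.data.copy()
        for k, v in cols.items():
            df[k] = v
        return PointTable(df)

    def subset(self, mask) -> "PointTable":
        return PointTable(self.data.loc[np.asarray(mask)].reset_index(drop=True))


@dataclass
class PolygonSet:
    """A labelled collection of planar polygons (shapely geometries)."""

    polygons: list[BaseGeometry]
    label: str = ""

    def __post_init__(self) -> None:
        for geom in self.polygons:
            if geom.geom_type not in ("Polygon", "MultiPolygon"):
                raise ValueError(f"expected Polygon/MultiPolygon, got {geom.geom_type}")
            if not geom.is_valid:
                raise ValueError(f"invalid (self-intersecting?) polygon in set {self.label!r}")
            if geom.area <= 0:
                raise ValueError("polygon with non-positive area")

    def __len__(self) -> int:
        return len(self.polygons)

    def union(self) -> BaseGeometry:
        import shapely

        return shapely.union_all(self.polygons) if self.polygons else _shapely_shape(
            {"type": "Polygon", "coordinates": []}
        )
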