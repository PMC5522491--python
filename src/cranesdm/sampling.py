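"""Training-design construction: background lattice, covariate extraction
and ratio-controlled pseudo-absence sampling.

The design mirrors standard presence/pseudo-absence SDM practice: presences
are the observed breeding locations, and background ("pseudo-absence")
points are drawn uniformly from a regular lattice over the study area at a
fixed absences-per-presence ratio (default 100, i.e. 183 presences pair
with 18,300 pseudo-absences).  Lattice cells already holding a presence are
excluded so no location carries both labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import PointTable, RasterGrid, check_aligned

__all__ = [
    "TrainingDesign",
    "make_lattice",
    "extract_covariates",
    "sample_pseudo_absences",
    "assemble_design",
]

logger = logging.getLogger(__name__)

#: covariates treated as categorical (one-hot encoded downstream)
DEFAULT_CATEGORICAL = ("Landcv",)


@dataclass
class TrainingDesign:
    """Feature matrix + labels for the suitability classifier.

    ``features`` holds raw covariate columns (categoricals not yet
    encoded); ``labels`` is 1 for presence, 0 for pseudo-absence.
    """

    presence: PointTable
    pseudo_absence: PointTable
    ratio: int
    features: pd.DataFrame
    labels: np.ndarray
    categorical: tuple[str, ...] = DEFAULT_CATEGORICAL

    @property
    def n_presence(self) -> int:
        return int(self.labels.sum())

    @property
    def n_absence(self) -> int:
        return int((self.labels == 0).sum())

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)


def make_lattice(
    bounds: tuple[float, float, float, float],
    spacing: float,
) -> PointTable:
    """Regular point lattice covering ``bounds`` = (xmin, ymin, xmax, ymax).

    Points sit at the centres of spacing-sized cells packed from the
    top-left corner; partial cells at the right/bottom are dropped, so the
    count is floor(width/spacing) * floor(height/spacing).
    """
    xmin, ymin, xmax, ymax = bounds
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"degenerate bounds {bounds}")
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    nx = int(np.floor((xmax - xmin) / spacing))
    ny = int(np.floor((ymax - ymin) / spacing))
    if nx < 1 or ny < 1:
        raise ValueError(
            f"spacing {spacing} exceeds bounds extent "
            f"({xmax - xmin} x {ymax - ymin})"
        )
    cols, rows = np.meshgrid(np.arange(nx), np.arange(ny))
    x = xmin + (cols.ravel() + 0.5) * spacing
    y = ymax - (rows.ravel() + 0.5) * spacing
    return PointTable.from_xy(x, y, role="pseudo_absence")


def extract_covariates(
    points: PointTable,
    stack: Mapping[str, RasterGrid],
) -> PointTable:
    """Attach each layer's cell value (half-open cell rule) to every point.

    Points outside the grid or hitting nodata in any layer are *flagged*
    (boolean ``flagged`` column), never silently dropped.
    """
    grids = list(stack.values())
    check_aligned(*grids)
    template = grids[0]
    row, col = template.index_of(points.x, points.y)
    inside = (row >= 0) & (row < template.rows) & (col >= 0) & (col < template.cols)
    flagged = ~inside
    r_safe = np.clip(row, 0, template.rows - 1)
    c_safe = np.clip(col, 0, template.cols - 1)
    cols = {}
    for name, grid in stack.items():
        vals = np.asarray(grid.values)[r_safe, c_safe].astype(float)
        nod = grid.nodata_mask()[r_safe, c_safe]
        flagged = flagged | nod
        vals = np.where(inside, vals, np.nan)
        cols[name] = vals
    out = points.with_columns(**cols, flagged=flagged)
    n_flag = int(flagged.sum())
    if n_flag:
        logger.warning("%d of %d points flagged (out of bounds or nodata)",
                       n_flag, len(points))
    return out


def sample_pseudo_absences(
    lattice: PointTable,
    presence: PointTable,
    ratio: int = 100,
    seed: int = 0,
    exclude_presence_cells: bool = True,
    cell_size: float | None = None,
) -> PointTable:
    """Uniform random sample of lattice points as pseudo-absences.

    Draws exactly ``ratio * len(presence)`` points without replacement from
    lattice points whose cell does not contain a presence (exclusion can be
    disabled).  Cell membership is judged at the lattice's own spacing:
    a lattice point is excluded when a presence lies within half a spacing
    of it in both axes.  Deterministic per seed.
    """
    if ratio < 1:
        raise ValueError(f"ratio must be a positive integer, got {ratio}")
    n_needed = ratio * len(presence)
    lx, ly = lattice.x, lattice.y
    keep = np.ones(len(lattice), dtype=bool)
    if exclude_presence_cells and len(presence):
        if cell_size is None:
            # infer lattice spacing from the most common x gap
            ux = np.unique(lx)
            cell_size = float(np.min(np.diff(ux))) if len(ux) > 1 else np.inf
        half = cell_size / 2.0
        for px, py in zip(presence.x, presence.y):
            keep &= ~((np.abs(lx - px) <= half) & (np.abs(ly - py) <= half))
    n_avail = int(keep.sum())
    if n_avail < n_needed:
        raise ValueError(
            f"lattice too small for pseudo-absence sampling: need {n_needed} "
            f"points but only {n_avail} lattice cells are free of presences"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(np.flatnonzero(keep), size=n_needed, replace=False)
    chosen.sort()
    sub = lattice.data.iloc[chosen].reset_index(drop=True).copy()
    sub["role"] = "pseudo_absence"
    start = (presence.data["id"].max() + 1) if len(presence) else 0
    sub["id"] = np.arange(start, start + len(sub), dtype=np.int64)
    return PointTable(sub)


def assemble_design(
    presence: PointTable,
    pseudo_absence: PointTable,
    stack: Mapping[str, RasterGrid] | None = None,
    ratio: int | None = None,
    categorical: Sequence[str] = DEFAULT_CATEGORICAL,
) -> TrainingDesign:
    """Stack presence (label 1) on pseudo-absences (label 0) into a design.

    Both tables must already carry covariates (pass ``stack`` to extract
    here).  Flagged rows (nodata / out of bounds) are dropped with a
    warning.  Categorical covariates are recorded on the design and one-hot
    encoded by the model, not coerced to numeric here.
    """
    if stack is not None:
        presence = extract_covariates(presence, stack)
        pseudo_absence = extract_covariates(pseudo_absence, stack)
    if len(pseudo_absence) == 0:
        raise ValueError("ratio violated: empty pseudo-absence table")
    p_names = presence.covariate_names
    a_names = pseudo_absence.covariate_names
    if p_names != a_names:
        raise ValueError(
            f"covariate mismatch between tables: {p_names} vs {a_names}"
        )
    if not p_names:
        raise ValueError("tables carry no covariates; extract first")
    shared = set(presence.data["id"]) & set(pseudo_absence.data["id"])
    if shared:
        raise ValueError(f"duplicate point ids across tables: {sorted(shared)[:5]}")

    if ratio is None:
        if len(pseudo_absence) % len(presence):
            warnings.warn(
                f"absence count {len(pseudo_absence)} is not an integer multiple "
                f"of presence count {len(presence)}"
            )
        ratio = max(1, len(pseudo_absence) // len(presence))

    def _clean(tbl: PointTable, what: str) -> PointTable:
        fl = tbl.flagged
        if fl.any():
            logger.warning("dropping %d flagged %s rows from design", int(fl.sum()), what)
        return tbl.subset(~fl)

    presence = _clean(presence, "presence")
    pseudo_absence = _clean(pseudo_absence, "pseudo-absence")
    feats = pd.concat(
        [presence.covariates, pseudo_absence.covariates], ignore_index=True
    )
    labels = np.concatenate(
        [np.ones(len(presence), dtype=int), np.zeros(len(pseudo_absence), dtype=int)]
    )
    cat = tuple(c for c in categorical if c in feats.columns)
    return TrainingDesign(
        presence=presence,
        pseudo_absence=pseudo_absence,
        ratio=ratio,
        features=feats,
        labels=labels,
        categorical=cat,
    )
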