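"""Prediction surfaces: inverse-distance-weighted interpolation of scored
lattice points onto a raster, and threshold binarization.

IDW assigns each cell centre the weighted mean of its k nearest scored
points with weights d^(-power); a cell coincident with a point takes that
point's value exactly.  When every cell centre hosts a scored point the
interpolation is the identity, so scoring the full lattice reproduces the
per-cell model output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .grid import PointTable, RasterGrid

__all__ = ["PredictionSurface", "idw_interpolate", "binarize", "make_surface"]

MASK_NODATA = 255


def idw_interpolate(
    scored_points: PointTable,
    target: RasterGrid,
    power: float = 2.0,
    k_neighbors: int = 12,
) -> RasterGrid:
    """Interpolate point RIOs onto the target grid's cell centres.

    Each centre receives sum(w_i * rio_i) / sum(w_i) over its k nearest
    points, w_i = d_i^(-power); zero distance short-circuits to the point's
    own value.  Output values lie within [min, max] of the inputs.
    """
    if power <= 0:
        raise ValueError(f"power must be positive, got {power}")
    if k_neighbors < 1:
        raise ValueError(f"k_neighbors must be >= 1, got {k_neighbors}")
    pts = scored_points.subset(~scored_points.flagged) \
        if scored_points.flagged.any() else scored_points
    rio = np.asarray(pts.rio, dtype=float)
    ok = ~np.isnan(rio)
    xy = np.column_stack([pts.x, pts.y])[ok]
    rio = rio[ok]
    if len(rio) == 0:
        raise ValueError("no scored points to interpolate")
    k = min(k_neighbors, len(rio))
    tree = cKDTree(xy)
    cx, cy = target.centers()
    queries = np.column_stack([cx.ravel(), cy.ravel()])
    dist, idx = tree.query(queries, k=k)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    vals = rio[idx]
    exact = dist[:, 0] == 0.0
    with np.errstate(divide="ignore"):
        w = dist ** (-power)
    out = np.empty(len(queries))
    out[exact] = vals[exact, 0]
    ne = ~exact
    out[ne] = (w[ne] * vals[ne]).sum(axis=1) / w[ne].sum(axis=1)
    return target.with_values(out.reshape(target.shape), name="rio", nodata=None)


def binarize(rio: RasterGrid, threshold: float) -> RasterGrid:
    """Binary presence mask: 1 where RIO >= threshold (inclusive), else 0.

    Nodata cells propagate as the mask's own nodata sentinel (255).
    """
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    nod = rio.nodata_mask()
    mask = (np.asarray(rio.values, dtype=float) >= threshold).astype(np.uint8)
    mask[nod] = MASK_NODATA
    return rio.with_values(mask, name="presence_mask",
                           nodata=MASK_NODATA if nod.any() else None)


@dataclass
class PredictionSurface:
    """Continuous RIO raster plus its binary map and the threshold used."""

    rio: RasterGrid
    mask: RasterGrid
    threshold: float


def make_surface(scored_points: PointTable, template: RasterGrid,
                 threshold: float, power: float = 2.0,
                 k_neighbors: int = 12) -> PredictionSurface:
    rio = idw_interpolate(scored_points, template, power=power,
                         k_neighbors=k_neighbors)
    return PredictionSurface(rio=rio, mask=binarize(rio, threshold),
                             threshold=threshold)
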