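"""Conservation-gap overlay.

A conservation gap is predicted presence habitat that is both under
meaningful human pressure (human-influence index, HII, at or above a
safety cut-off — default 10) and outside every protected area.  Leaving
pristine-but-unprotected habitat out of the gaps keeps the result focused
on places where protection is actually actionable.

All areas are counted in cells (equal-area planar grid), so fractions are
cell-count ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import shapely

from .grid import PolygonSet, RasterGrid, check_aligned

__all__ = [
    "GapSummary",
    "reclassify_hii",
    "rasterize_polygons",
    "conservation_gaps",
]

HII_MAX = 64


def reclassify_hii(hii: RasterGrid, interval: int = 5) -> RasterGrid:
    """Bin HII values into classes of ``interval`` units: class floor(v/interval).

    Values must be integers in [0, 64]; the maximum value 64 falls in the
    final class (floor(64/5) = 12).
    """
    vals = np.asarray(hii.values)
    nod = hii.nodata_mask()
    live = vals[~nod]
    if ((live < 0) | (live > HII_MAX)).any():
        bad = live[(live < 0) | (live > HII_MAX)]
        raise ValueError(f"HII values outside [0, {HII_MAX}]: e.g. {bad[:5]}")
    classes = np.floor_divide(vals.astype(np.int64), interval)
    out = hii.with_values(classes.astype(np.int32), name="hii_class",
                          nodata=hii.nodata)
    if hii.nodata is not None:
        out.values[nod] = hii.nodata
    return out


def rasterize_polygons(polys: PolygonSet, template: RasterGrid) -> RasterGrid:
    """Burn polygons into a 0/1 mask on the template grid (centre rule).

    A cell is 1 iff its centre lies inside (or on the boundary of) any
    polygon.
    """
    mask = np.zeros(template.shape, dtype=np.uint8)
    if len(polys) == 0:
        import warnings

        warnings.warn("empty polygon set rasterizes to an all-zero mask")
        return template.with_values(mask, name=polys.label or "mask", nodata=None)
    union = shapely.union_all(polys.polygons)
    cx, cy = template.centers()
    inside = shapely.intersects_xy(union, cx.ravel(), cy.ravel())
    mask.flat[inside] = 1
    return template.with_values(mask, name=polys.label or "mask", nodata=None)


@dataclass
class GapSummary:
    """Area fractions of the conservation-status overlay.

    All fractions are relative to the predicted-presence area except
    ``protected_of_pressured``, which is relative to the pressured
    (HII >= cutoff) presence area.
    """

    n_presence_cells: int
    protected_fraction: float          # presence inside protected areas
    hii_class_shares: dict[int, float]  # share of presence cells per HII class
    pressured_fraction: float          # presence with HII >= cutoff
    protected_of_pressured: float      # of those, fraction protected
    gap_fraction: float                # presence & HII >= cutoff & unprotected
    gap_mask: RasterGrid
    hii_cutoff: int

    def marginal_product(self) -> float:
        """Consistency identity: gap fraction recomputed from the two
        marginals, pressured * (1 - protected_of_pressured)."""
        return self.pressured_fraction * (1.0 - self.protected_of_pressured)


def conservation_gaps(
    presence_mask: RasterGrid,
    hii: RasterGrid,
    protected_mask: RasterGrid,
    hii_cutoff: int = 10,
    class_interval: int = 5,
) -> GapSummary:
    """Overlay the binary prediction, HII and protection into a GapSummary.

    gap = presence AND (HII >= hii_cutoff) AND (NOT protected).
    """
    check_aligned(presence_mask, hii, protected_mask)
    nod = (presence_mask.nodata_mask() | hii.nodata_mask()
           | protected_mask.nodata_mask())
    pres = (np.asarray(presence_mask.values) == 1) & ~nod
    prot = (np.asarray(protected_mask.values) == 1) & ~nod
    hii_vals = np.asarray(hii.values)
    pressured = (hii_vals >= hii_cutoff) & ~nod

    n_pres = int(pres.sum())
    if n_pres == 0:
        raise ValueError("presence mask has no presence cells")

    classes = reclassify_hii(hii, interval=class_interval).values
    shares: dict[int, float] = {}
    cls_in_pres = classes[pres]
    for cls in np.unique(cls_in_pres):
        shares[int(cls)] = float((cls_in_pres == cls).sum() / n_pres)

    pres_pressured = pres & pressured
    n_pressured = int(pres_pressured.sum())
    gap = pres_pressured & ~prot
    gap_values = gap.astype(np.uint8)
    gap_values[nod] = 255

    return GapSummary(
        n_presence_cells=n_pres,
        protected_fraction=float((pres & prot).sum() / n_pres),
        hii_class_shares=shares,
        pressured_fraction=n_pressured / n_pres,
        protected_of_pressured=(
            float((pres_pressured & prot).sum() / n_pressured)
            if n_pressured else 0.0
        ),
        gap_fraction=float(gap.sum() / n_pres),
        gap_mask=presence_mask.with_values(
            gap_values, name="conservation_gap",
            nodata=255 if nod.any() else None
        ),
        hii_cutoff=hii_cutoff,
    )
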