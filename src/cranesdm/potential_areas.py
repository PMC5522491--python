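"""Potential (unoccupied but predicted-suitable) range delineation.

Predicted presence pixels within a dispersal buffer (default 67 km) of any
known breeding-range polygon or breeding record are removed; the remaining
pixels are aggregated into 8-connected clusters, and a moving-disc point
density of presence pixels highlights focal cells for field-survey
prioritization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import PointTable, PolygonSet, RasterGrid

__all__ = [
    "ClusterTable",
    "DensitySurface",
    "buffer_exclude",
    "aggregate_clusters",
    "point_density",
    "rank_focal_regions",
]


def buffer_exclude(
    presence_mask: RasterGrid,
    known_ranges: PolygonSet | None = None,
    records: PointTable | None = None,
    distance: float = 67_000.0,
) -> RasterGrid:
    """Zero out presence cells within ``distance`` (boundary-inclusive
    Euclidean metres) of any record point or known-range polygon.

    Cells outside the buffer, and non-presence cells, are unchanged.  Empty
    geometry leaves the mask untouched.
    """
    if distance < 0:
        raise ValueError(f"distance must be >= 0, got {distance}")
    vals = np.asarray(presence_mask.values).copy()
    cx, cy = presence_mask.centers()
    within = np.zeros(presence_mask.shape, dtype=bool)
    if records is not None and len(records):
        tree = cKDTree(np.column_stack([records.x, records.y]))
        d, _ = tree.query(np.column_stack([cx.ravel(), cy.ravel()]), k=1)
        within |= (d.reshape(presence_mask.shape) <= distance)
    if known_ranges is not None and len(known_ranges):
        union = shapely.union_all(known_ranges.polygons)
        pts = shapely.points(np.column_stack([cx.ravel(), cy.ravel()]))
        d = shapely.distance(pts, union)  # 0 inside the polygon
        within |= (d.reshape(presence_mask.shape) <= distance)
    vals[within & (vals == 1)] = 0
    return presence_mask.with_values(vals, name="potential_mask",
                                     nodata=presence_mask.nodata)


@dataclass
class ClusterTable:
    """Connected clusters of potential-range pixels.

    ``table`` columns: cluster_id, pixels, share_pct (of all potential
    pixels, including unassigned ones), centroid_x, centroid_y.
    ``unassigned_pixels`` counts pixels in components below the size floor.
    """

    table: pd.DataFrame
    labels: RasterGrid           # 0 = background, i = cluster id
    total_pixels: int
    unassigned_pixels: int

    def __len__(self) -> int:
        return len(self.table)

    def bounding_polygon(self, cluster_id: int) -> shapely.Geometry:
        """Union of the cluster's cell squares (axis-aligned boxes)."""
        lab = np.asarray(self.labels.values)
        rr, cc = np.nonzero(lab == cluster_id)
        s = self.labels.cell_size
        boxes = [
            shapely.box(
                self.labels.origin_x + c * s,
                self.labels.origin_y - (r + 1) * s,
                self.labels.origin_x + (c + 1) * s,
                self.labels.origin_y - r * s,
            )
            for r, c in zip(rr, cc)
        ]
        return shapely.union_all(boxes)


def aggregate_clusters(mask: RasterGrid, min_pixels: int = 10,
                       connectivity: int = 8) -> ClusterTable:
    """Label 8-connected components of a binary mask as clusters.

    Components smaller than ``min_pixels`` stay unassigned (and out of the
    table) but still count toward the pixel total, so cluster shares sum
    to <= 100%.
    """
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    binary = np.asarray(mask.values) == 1
    structure = (np.ones((3, 3), dtype=int) if connectivity == 8
                 else ndimage.generate_binary_structure(2, 1))
    labeled, n_comp = ndimage.label(binary, structure=structure)
    total = int(binary.sum())
    rows = []
    out_labels = np.zeros_like(labeled)
    unassigned = 0
    next_id = 1
    if n_comp:
        counts = np.bincount(labeled.ravel())[1:]  # per original component
        order = np.argsort(-counts, kind="stable")
        for comp in order + 1:
            cnt = int(counts[comp - 1])
            if cnt < min_pixels:
                unassigned += cnt
                continue
            sel = labeled == comp
            rr, cc = np.nonzero(sel)
            cxs, cys = mask.cell_center(rr, cc)
            out_labels[sel] = next_id
            rows.append({
                "cluster_id": next_id,
                "pixels": cnt,
                "share_pct": 100.0 * cnt / total if total else 0.0,
                "centroid_x": float(cxs.mean()),
                "centroid_y": float(cys.mean()),
            })
            next_id += 1
    table = pd.DataFrame(
        rows, columns=["cluster_id", "pixels", "share_pct",
                       "centroid_x", "centroid_y"]
    )
    return ClusterTable(
        table=table,
        labels=mask.with_values(out_labels.astype(np.int32),
                                name="clusters", nodata=None),
        total_pixels=total,
        unassigned_pixels=unassigned,
    )


@dataclass
class DensitySurface:
    """Presence-pixel density (pixels per unit area within a disc)."""

    density: RasterGrid
    radius: float


def point_density(mask: RasterGrid, radius: float) -> DensitySurface:
    """Moving-disc density of presence pixels, centre-to-centre distances.

    Each cell's value is the count of presence-pixel centres within
    ``radius`` of its own centre, divided by the disc area pi * r^2.  No
    edge correction: the denominator is the full disc everywhere.
    """
    if radius < mask.cell_size:
        raise ValueError(
            f"radius ({radius}) must be at least one cell ({mask.cell_size})"
        )
    binary = (np.asarray(mask.values) == 1).astype(float)
    r_cells = radius / mask.cell_size
    half = int(np.floor(r_cells))
    offs = np.arange(-half, half + 1)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    kernel = (np.hypot(oy, ox) <= r_cells).astype(float)
    counts = ndimage.convolve(binary, kernel, mode="constant", cval=0.0)
    dens = counts / (np.pi * radius ** 2)
    return DensitySurface(
        density=mask.with_values(dens, name="pixel_density", nodata=None),
        radius=radius,
    )


def rank_focal_regions(clusters: ClusterTable, density: DensitySurface,
                       top_k: int | None = None
                       ) -> list[tuple[int, tuple[int, int], float]]:
    """Order clusters by pixel share and find each one's density peak.

    Returns (cluster_id, (row, col) of the densest cell, peak density) for
    the top_k clusters.  Ties in share break by pixel count, then by
    cluster id.
    """
    if len(clusters) == 0:
        raise ValueError("no clusters to rank")
    df = clusters.table.sort_values(
        ["share_pct", "pixels", "cluster_id"],
        ascending=[False, False, True], kind="stable",
    )
    if top_k is None:
        top_k = len(df)
    elif top_k > len(df):
        warnings.warn(f"top_k={top_k} exceeds cluster count {len(df)}; returning all")
        top_k = len(df)
    lab = np.asarray(clusters.labels.values)
    dens = np.asarray(density.density.values)
    out = []
    for cid in df["cluster_id"].head(top_k):
        sel = lab == cid
        masked = np.where(sel, dens, -np.inf)
        flat = int(np.argmax(masked))
        r, c = np.unravel_index(flat, lab.shape)
        out.append((int(cid), (int(r), int(c)), float(dens[r, c])))
    return out
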