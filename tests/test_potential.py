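"""Potential-range delineation: buffer exclusion geometry, connected-
component clustering against a flood-fill oracle, disc point density, and
focal-region ranking."""

import numpy as np
import pytest
from shapely.geometry import box

from cranesdm.grid import PointTable, PolygonSet, RasterGrid
from cranesdm.potential_areas import (aggregate_clusters, buffer_exclude,
                                      point_density, rank_focal_regions)


def mask_grid(values, cell=1000.0):
    return RasterGrid(np.asarray(values, dtype=np.uint8), 0.0, 0.0, cell)


def flood_fill_label(binary):
    """Brute-force 8-connected component labelling oracle."""
    binary = np.asarray(binary, dtype=bool)
    labels = np.zeros(binary.shape, dtype=int)
    nxt = 0
    for r0 in range(binary.shape[0]):
        for c0 in range(binary.shape[1]):
            if binary[r0, c0] and labels[r0, c0] == 0:
                nxt += 1
                stack = [(r0, c0)]
                labels[r0, c0] = nxt
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < binary.shape[0]
                                    and 0 <= cc < binary.shape[1]
                                    and binary[rr, cc] and labels[rr, cc] == 0):
                                labels[rr, cc] = nxt
                                stack.append((rr, cc))
    return labels, nxt


class TestBufferExclude:
    def test_no_geometry_is_identity(self):
        m = mask_grid(np.ones((5, 5)))
        out = buffer_exclude(m)
        assert np.array_equal(out.values, m.values)

    def test_distance_zero_removes_only_containing_cell(self):
        m = mask_grid(np.ones((5, 5)))
        rec = PointTable.from_xy([2500.0], [-2500.0], "presence")
        out = buffer_exclude(m, records=rec, distance=0.0)
        assert out.values.sum() == 24
        assert out.values[2, 2] == 0

    def test_record_at_centre_removes_ring(self):
        """Distance 1.5 cells from a cell centre reaches the 4-neighbours
        (1 cell) and diagonals (sqrt 2 cells): a 3x3 block goes."""
        m = mask_grid(np.ones((7, 7)))
        rec = PointTable.from_xy([3500.0], [-3500.0], "presence")
        out = buffer_exclude(m, records=rec, distance=1500.0)
        removed = np.argwhere(out.values == 0)
        assert len(removed) == 9
        assert set(map(tuple, removed)) == {
            (r, c) for r in (2, 3, 4) for c in (2, 3, 4)}

    def test_polygon_buffer_inclusive(self):
        m = mask_grid(np.ones((5, 5)))
        rng_poly = PolygonSet([box(0, -1000, 1000, 0)], label="cbr")
        out = buffer_exclude(m, known_ranges=rng_poly, distance=0.0)
        assert out.values[0, 0] == 0
        assert out.values.sum() == 24

    def test_monotone_in_distance(self):
        rng = np.random.default_rng(0)
        m = mask_grid(rng.integers(0, 2, (12, 12)))
        rec = PointTable.from_xy([6000.0, 2000.0], [-3000.0, -9000.0],
                                 "presence")
        prev = None
        for d in (0.0, 2000.0, 5000.0, 50_000.0):
            out = buffer_exclude(m, records=rec, distance=d)
            kept = set(map(tuple, np.argwhere(out.values == 1)))
            if prev is not None:
                assert kept <= prev
            prev = kept
        assert len(prev) == 0  # huge distance empties the mask


class TestAggregateClusters:
    def test_solid_block_single_cluster(self):
        vals = np.zeros((9, 9))
        vals[2:7, 2:7] = 1
        ct = aggregate_clusters(mask_grid(vals), min_pixels=10)
        assert len(ct) == 1
        assert ct.table.pixels.iloc[0] == 25
        assert ct.table.share_pct.iloc[0] == pytest.approx(100.0)

    def test_two_blocks_share_arithmetic(self):
        vals = np.zeros((30, 30))
        vals[0:5, 0:5] = 1      # 25 px
        vals[10:25, 10:15] = 1  # 75 px
        ct = aggregate_clusters(mask_grid(vals), min_pixels=10)
        assert sorted(ct.table.share_pct.round(6)) == [25.0, 75.0]

    def test_small_component_unassigned(self):
        vals = np.zeros((20, 20))
        vals[0:5, 0:5] = 1
        vals[15, 15] = 1
        ct = aggregate_clusters(mask_grid(vals), min_pixels=10)
        assert len(ct) == 1
        assert ct.unassigned_pixels == 1
        assert ct.table.pixels.sum() + ct.unassigned_pixels == ct.total_pixels

    def test_empty_mask(self):
        ct = aggregate_clusters(mask_grid(np.zeros((5, 5))))
        assert len(ct) == 0 and ct.total_pixels == 0

    def test_diagonal_touch_is_connected(self):
        vals = np.zeros((4, 4))
        vals[0, 0] = vals[1, 1] = vals[2, 2] = 1
        ct = aggregate_clusters(mask_grid(vals), min_pixels=3)
        assert len(ct) == 1

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            binary = rng.random((20, 20)) < 0.35
            oracle_labels, n_oracle = flood_fill_label(binary)
            ct = aggregate_clusters(mask_grid(binary.astype(int)),
                                    min_pixels=1)
            assert len(ct) == n_oracle
            oracle_sizes = sorted(np.bincount(oracle_labels.ravel())[1:])
            assert sorted(ct.table.pixels) == oracle_sizes
            # conservation: assigned + unassigned == total
            assert ct.table.pixels.sum() + ct.unassigned_pixels == \
                int(binary.sum())


class TestPointDensity:
    def test_empty_mask_zero_surface(self):
        d = point_density(mask_grid(np.zeros((6, 6))), radius=2000.0)
        assert (d.density.values == 0).all()

    def test_single_pixel_peak(self):
        vals = np.zeros((9, 9))
        vals[4, 4] = 1
        d = point_density(mask_grid(vals), radius=1000.0)
        peak = d.density.values[4, 4]
        assert peak == pytest.approx(1 / (np.pi * 1000.0 ** 2))
        # the source pixel attains the maximum (4-neighbours at exactly one
        # cell distance tie under the boundary-inclusive disc)
        assert peak == d.density.values.max()

    def test_uniform_interior_constant(self):
        vals = np.ones((21, 21))
        r = 3000.0
        d = point_density(mask_grid(vals), radius=r)
        # disc-count oracle at an interior cell
        offs = np.arange(-3, 4)
        oy, ox = np.meshgrid(offs, offs, indexing="ij")
        n_in_disc = (np.hypot(oy, ox) * 1000.0 <= r).sum()
        expected = n_in_disc / (np.pi * r ** 2)
        interior = d.density.values[5:16, 5:16]
        assert np.allclose(interior, expected)

    def test_radius_below_cell_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            point_density(mask_grid(np.ones((4, 4))), radius=500.0)


class TestRankFocalRegions:
    def _setup(self, blocks):
        vals = np.zeros((40, 40))
        for (r, c, size) in blocks:
            vals[r:r + size, c:c + size] = 1
        m = mask_grid(vals)
        ct = aggregate_clusters(m, min_pixels=4)
        dens = point_density(m, radius=2000.0)
        return ct, dens

    def test_ordered_by_share(self):
        ct, dens = self._setup([(0, 0, 8), (20, 20, 3), (30, 2, 5)])
        ranked = rank_focal_regions(ct, dens)
        sizes = [ct.table.set_index("cluster_id").loc[cid, "pixels"]
                 for cid, _, _ in ranked]
        assert sizes == sorted(sizes, reverse=True)

    def test_peak_cell_inside_cluster(self):
        ct, dens = self._setup([(0, 0, 6), (25, 25, 10)])
        for cid, (r, c), peak in rank_focal_regions(ct, dens):
            assert ct.labels.values[r, c] == cid
            assert peak == dens.density.values[r, c]

    def test_single_cluster(self):
        ct, dens = self._setup([(5, 5, 6)])
        ranked = rank_focal_regions(ct, dens)
        assert len(ranked) == 1

    def test_top_k_overflow_warns(self):
        ct, dens = self._setup([(5, 5, 6)])
        with pytest.warns(UserWarning, match="exceeds cluster count"):
            ranked = rank_focal_regions(ct, dens, top_k=5)
        assert len(ranked) == 1

    def test_empty_rejected(self):
        ct, dens = self._setup([(0, 0, 1)])  # below min size -> no clusters
        with pytest.raises(ValueError, match="no clusters"):
            rank_focal_regions(ct, dens)
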