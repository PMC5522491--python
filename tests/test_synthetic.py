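"""Virtual-landscape generator: determinism, range contracts, response
shapes, occurrence-sampling statistics, HII and protected-area synthesis."""

import numpy as np
import pytest
from scipy import stats

from cranesdm import synthetic as syn
from cranesdm.gap_analysis import rasterize_polygons


class TestCovariates:
    def test_deterministic_per_seed(self):
        a = syn.generate_covariates((24, 24), seed=1)
        b = syn.generate_covariates((24, 24), seed=1)
        for name in a:
            assert np.array_equal(a[name].values, b[name].values)

    def test_seeds_differ(self):
        a = syn.generate_covariates((64, 64), seed=1)
        b = syn.generate_covariates((64, 64), seed=2)
        frac = (a["Altitude"].values != b["Altitude"].values).mean()
        assert frac >= 0.01

    def test_range_contracts(self, small_truth):
        stack = small_truth.stack
        for name, (lo, hi) in syn.COVARIATE_RANGES.items():
            vals = stack[name].values
            assert vals.min() >= lo and vals.max() <= hi, name

    def test_landcover_classes(self, small_truth):
        classes = np.unique(small_truth.stack["Landcv"].values)
        assert len(classes) >= 3
        assert 1 in classes  # herbaceous code

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            syn.generate_covariates((8, 8), seed=0)


class TestSuitability:
    def test_all_unit_responses_give_prevalence(self, small_truth):
        spec = syn.ResponseSpec(responses=(), prevalence=0.7)
        suit = syn.true_suitability(small_truth.stack, spec)
        assert np.allclose(suit.values, 0.7)

    def test_sigmoid_far_below_inflection_is_tiny(self):
        resp = syn.SigmoidResponse("Altitude", 2800.0, 115.0, +1)
        assert resp(np.array([1000.0]))[0] < 0.05

    def test_sigmoid_at_inflection_is_half(self):
        for resp in syn.default_response_spec().responses:
            if isinstance(resp, syn.SigmoidResponse):
                assert resp(np.array([resp.inflection]))[0] == pytest.approx(0.5)

    def test_missing_layer_raises(self, small_truth):
        spec = syn.ResponseSpec(
            responses=(syn.SigmoidResponse("Bio_99", 0.0, 1.0),))
        with pytest.raises(KeyError, match="Bio_99"):
            syn.true_suitability(small_truth.stack, spec)

    def test_suitability_in_unit_interval(self, small_truth):
        v = small_truth.suitability.values
        assert v.min() >= 0.0 and v.max() <= 1.0


class TestOccurrences:
    def test_counts_and_disjoint(self, small_truth):
        pres, test = syn.sample_occurrences(small_truth.suitability,
                                            n_presence=183, n_test=102, seed=0)
        assert len(pres) == 183 and len(test) == 102
        pres_xy = set(zip(pres.x, pres.y))
        test_xy = set(zip(test.x, test.y))
        assert not pres_xy & test_xy

    def test_deterministic(self, small_truth):
        a, _ = syn.sample_occurrences(small_truth.suitability, 50, 10, seed=3)
        b, _ = syn.sample_occurrences(small_truth.suitability, 50, 10, seed=3)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)

    def test_single_positive_cell(self):
        from cranesdm.grid import RasterGrid

        vals = np.zeros((20, 20))
        vals[4, 9] = 0.8
        g = RasterGrid(vals, 0.0, 0.0, 1000.0)
        pres, test = syn.sample_occurrences(g, 1, 0, seed=0)
        assert len(pres) == 1 and len(test) == 0
        assert pres.x[0] == 9500.0 and pres.y[0] == -4500.0

    def test_insufficient_cells_raise(self):
        from cranesdm.grid import RasterGrid

        g = RasterGrid(np.zeros((20, 20)), 0, 0, 1000.0)
        with pytest.raises(ValueError, match="positive suitability"):
            syn.sample_occurrences(g, 5, 5, seed=0)

    def test_sampling_prefers_suitable_cells(self, small_truth):
        """Mean true suitability at presences beats the landscape mean."""
        s = small_truth.suitability
        land_mean = s.values.mean()
        for seed in range(20):
            pres, _ = syn.sample_occurrences(s, 40, 0, seed=seed)
            r, c = s.index_of(pres.x, pres.y)
            assert s.values[r, c].mean() > land_mean

    def test_survey_region_restricts_sampling(self, small_truth):
        s = small_truth.suitability
        xmin, ymin, xmax, ymax = s.bounds
        region = ((xmin + xmax) / 2, ymin, xmax, ymax)
        pres, test = syn.sample_occurrences(s, 30, 10, seed=1, region=region)
        assert (pres.x >= region[0]).all() and (test.x >= region[0]).all()

    def test_frequencies_proportional_to_suitability(self):
        """Chi-square goodness of fit of sampled-cell frequencies against
        suitability-proportional weights, aggregated over a seed batch."""
        from cranesdm.grid import RasterGrid

        rng = np.random.default_rng(0)
        vals = rng.uniform(0.1, 1.0, (6, 6))
        g = RasterGrid(vals, 0.0, 0.0, 1000.0)
        counts = np.zeros(36)
        n_draws, batch = 10, 500
        for seed in range(batch):
            pres, _ = syn.sample_occurrences(g, n_draws, 0, seed=seed)
            r, c = g.index_of(pres.x, pres.y)
            np.add.at(counts, r * 6 + c, 1)
        # without-replacement draws flatten the tail slightly; compare the
        # empirical inclusion frequencies against a simulation oracle
        p = vals.ravel() / vals.sum()
        expected = np.zeros(36)
        orng = np.random.default_rng(999)
        for _ in range(batch):
            chosen = orng.choice(36, size=n_draws, replace=False, p=p)
            np.add.at(expected, chosen, 1)
        chi2 = ((counts - expected) ** 2 / np.maximum(expected, 1)).sum()
        pval = 1 - stats.chi2.cdf(chi2, df=35)
        assert pval > 0.01


class TestHII:
    def test_no_settlements_all_zero(self):
        hii = syn.generate_hii((32, 32), seed=0, settlement_count=0)
        assert (hii.values == 0).all()

    def test_clipped_to_64(self):
        for seed in range(5):
            hii = syn.generate_hii((32, 32), seed=seed, settlement_count=40)
            assert hii.values.max() <= 64 and hii.values.min() >= 0

    def test_decays_with_distance_to_settlement(self):
        hii = syn.generate_hii((48, 48), seed=3, settlement_count=6)
        vals = hii.values
        peaks = np.argwhere(vals >= np.percentile(vals[vals > 0], 99))
        rr, cc = np.meshgrid(np.arange(48), np.arange(48), indexing="ij")
        d = np.min(
            [np.hypot(rr - p[0], cc - p[1]) for p in peaks], axis=0)
        rho = stats.spearmanr(d.ravel(), vals.ravel()).statistic
        assert rho < -0.5


class TestProtectedAreas:
    def test_zero_coverage_empty(self):
        assert len(syn.generate_protected_areas((32, 32), 0.0, seed=0)) == 0

    def test_coverage_within_band(self, small_truth):
        pas = syn.generate_protected_areas((32, 32), 0.25, seed=7)
        template = small_truth.suitability
        mask = rasterize_polygons(pas, template)
        frac = mask.values.mean()
        assert 0.20 <= frac <= 0.30

    def test_polygons_within_bounds(self):
        pas = syn.generate_protected_areas((32, 32), 0.3, seed=2)
        for poly in pas.polygons:
            xmin, ymin, xmax, ymax = poly.bounds
            assert 0 <= xmin and xmax <= 32_000
            assert -32_000 <= ymin and ymax <= 0

    def test_full_coverage_rejected(self):
        with pytest.raises(ValueError, match="coverage_fraction"):
            syn.generate_protected_areas((32, 32), 1.0, seed=0)


def test_truth_regenerates_exactly():
    a = syn.make_truth((24, 24), seed=11)
    b = syn.make_truth((24, 24), seed=11)
    assert np.array_equal(a.suitability.values, b.suitability.values)
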