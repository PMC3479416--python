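"""Correlation, Manhattan distance, offset averaging, critical spacing."""

import numpy as np
import pytest

from chidist.compare import DadfComparison, averaged_comparison, \
    correlation_significance, critical_spacing, manhattan, pearson, \
    pearson_decomposition
from chidist.dadf import DADF, build_dadf, make_grid


def dadf_from_probs(probs, res_type="SER", spacing=None):
    probs = np.asarray(probs, dtype=float)
    spacing = spacing if spacing is not None else 360.0 / len(probs)
    g = make_grid(spacing, res_type)
    assert g.m == len(probs)
    return DADF(grid=g, probs=probs, n_samples=100)


class TestPearson:
    def test_self_correlation_is_exactly_one(self, rng):
        probs = rng.dirichlet(np.ones(12))
        d = dadf_from_probs(probs, spacing=30.0)
        assert pearson(d, d) == 1.0

    def test_exact_anticorrelation(self):
        x = dadf_from_probs([0.5, 0.5, 0.0, 0.0])
        y = dadf_from_probs([0.0, 0.0, 0.5, 0.5])
        assert pearson(x, y) == pytest.approx(-1.0)

    def test_uniform_dadf_is_undefined(self):
        x = dadf_from_probs([0.4, 0.3, 0.2, 0.1])
        y = dadf_from_probs([0.25, 0.25, 0.25, 0.25])
        assert pearson(x, y) is None

    def test_grid_mismatch_errors(self):
        x = dadf_from_probs([0.5, 0.5, 0.0, 0.0])
        y = DADF(grid=make_grid(90.0, "SER", (5.0,)),
                 probs=np.array([0.5, 0.5, 0.0, 0.0]), n_samples=10)
        with pytest.raises(ValueError):
            pearson(x, y)

    def test_matches_numpy_corrcoef(self, rng):
        x = dadf_from_probs(rng.dirichlet(np.ones(12)), spacing=30.0)
        y = dadf_from_probs(rng.dirichlet(np.ones(12)), spacing=30.0)
        expected = np.corrcoef(x.probs, y.probs)[0, 1]
        assert pearson(x, y) == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_common_cell_permutation(self, rng):
        x = rng.dirichlet(np.ones(12))
        y = rng.dirichlet(np.ones(12))
        perm = rng.permutation(12)
        r1 = pearson(dadf_from_probs(x, spacing=30.0),
                     dadf_from_probs(y, spacing=30.0))
        r2 = pearson(dadf_from_probs(x[perm], spacing=30.0),
                     dadf_from_probs(y[perm], spacing=30.0))
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_decomposition_identity(self, rng):
        x = dadf_from_probs(rng.dirichlet(np.ones(12)), spacing=30.0)
        y = dadf_from_probs(rng.dirichlet(np.ones(12)), spacing=30.0)
        cov, sd_x, sd_y, r = pearson_decomposition(x, y)
        assert r == pytest.approx(cov / (sd_x * sd_y), abs=1e-12)


class TestManhattan:
    def test_identical_dadfs_distance_zero(self, rng):
        d = dadf_from_probs(rng.dirichlet(np.ones(8)), spacing=45.0)
        assert manhattan(d, d) == 0.0

    def test_disjoint_supports_distance_one(self):
        x = dadf_from_probs([0.5, 0.5, 0.0, 0.0])
        y = dadf_from_probs([0.0, 0.0, 0.5, 0.5])
        assert manhattan(x, y) == 1.0

    def test_hand_summed_value(self):
        x = dadf_from_probs([0.5, 0.5, 0.0, 0.0])
        y = dadf_from_probs([0.5, 0.0, 0.5, 0.0])
        assert manhattan(x, y) == pytest.approx(0.5)

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(50):
            x, y, z = (dadf_from_probs(rng.dirichlet(np.ones(6)),
                                       spacing=60.0) for _ in range(3))
            assert manhattan(x, y) == pytest.approx(manhattan(y, x))
            assert manhattan(x, y) + manhattan(y, z) >= manhattan(x, z) - 1e-12
            assert 0.0 <= manhattan(x, y) <= 1.0


class TestSignificance:
    def test_zero_correlation_p_one(self):
        assert correlation_significance(0.0, 100) == pytest.approx(1.0)

    def test_moderate_correlation_many_cells(self):
        # oracle: t = 0.5*sqrt(98/0.75) = 5.7155, two-tailed tail mass on
        # 98 df is 1.1805e-7 (t-distribution tail, frozen)
        p = correlation_significance(0.5, 100)
        assert p < 1e-6
        assert p == pytest.approx(1.1805e-07, rel=1e-3)

    def test_monotone_in_r(self):
        ps = [correlation_significance(r, 50)
              for r in (0.1, 0.3, 0.5, 0.7, 0.9, 0.999)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert correlation_significance(1.0, 50) == 0.0

    def test_too_few_cells_undefined(self):
        assert correlation_significance(0.9, 2) is None


class TestCriticalSpacing:
    def test_first_crossing(self):
        series = {10: 0.60, 20: 0.68, 30: 0.72, 50: 0.80}
        assert critical_spacing(series) == 30

    def test_immediate(self):
        assert critical_spacing({10: 0.9}) == 10

    def test_never_reached(self):
        assert critical_spacing({10: 0.2, 30: 0.5, 90: 0.69}) is None

    def test_empty_series_errors(self):
        with pytest.raises(ValueError):
            critical_spacing({})


class TestAveragedComparison:
    def test_identical_pools_perfect_similarity(self, rng):
        samples = rng.uniform(-180, 180, size=(200, 1))
        for spacing in (10.0, 30.0, 90.0):
            res = averaged_comparison(samples, samples, "SER", spacing,
                                      n_repeats=20, rng=3)
            assert res.mean_r == 1.0
            assert res.sd_r == 0.0
            assert res.mean_d == 0.0

    def test_bit_reproducible_under_seed(self, rng):
        x = rng.uniform(-180, 180, size=(300, 1))
        y = rng.uniform(-180, 180, size=(300, 1))
        a = averaged_comparison(x, y, "SER", 30.0, rng=11)
        b = averaged_comparison(x, y, "SER", 30.0, rng=11)
        assert a.mean_r == b.mean_r and a.sd_r == b.sd_r
        assert a.mean_d == b.mean_d and a.sd_d == b.sd_d
        np.testing.assert_array_equal(a.repeats_r, b.repeats_r)

    def test_all_repeats_undefined_errors(self):
        # four samples 90 degrees apart give a uniform 4-cell DADF for
        # every split origin: zero variance in every repeat
        samples = np.array([[-135.0], [-45.0], [45.0], [135.0]])
        with pytest.raises(ValueError):
            averaged_comparison(samples, samples, "SER", 90.0, n_repeats=5,
                                rng=0)

    def test_model_results_surface(self, rng):
        x = rng.uniform(-180, 180, size=(100, 1))
        model = DadfComparison(x, x, "SER", 30.0, n_repeats=10,
                               category_pair="interface_B_vs_U")
        res = model.fit(rng=1)
        text = res.summary()
        assert "interface_B_vs_U" in text
        assert "mean correlation" in text
        assert res.m == 12 and res.n_x == res.n_y == 100

    def test_empty_pool_errors(self):
        with pytest.raises(ValueError):
            DadfComparison(np.empty((0, 1)), np.empty((0, 1)), "SER", 30.0)

    def test_mean_r_nondecreasing_in_spacing_on_average(self):
        """Coarser grids smooth the distributions: the offset-averaged
        correlation between jitter-perturbed pools rises with spacing
        (Spearman trend over the scan, averaged over seeds)."""
        from scipy.stats import spearmanr
        from chidist.synthetic import PairedPoolSpec, RotamerMixtureSpec, \
            perturb_paired, sample_pool
        spacings = (10.0, 30.0, 50.0, 70.0, 90.0)
        rhos = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            spec = RotamerMixtureSpec("SER", jitter_sd=10.0)
            pool = sample_pool(spec, 500, rng)
            paired = perturb_paired(pool, PairedPoolSpec(
                base=spec, flip_prob=0.05, jitter_sd=10.0, n=500), rng)
            rs = [averaged_comparison(pool.angles, paired.angles, "SER", sp,
                                      n_repeats=25, rng=seed).mean_r
                  for sp in spacings]
            rhos.append(spearmanr(spacings, rs).statistic)
        assert np.mean(rhos) > 0

    def test_manhattan_increases_with_flip_probability(self):
        """More rotamer flips at fixed jitter push the pools apart.

        Uses a skewed rotamer mixture: uniform flips erode the skew toward
        the uniform marginal, which the Manhattan distance sees directly
        (with equal rotamer weights the marginal is flip-invariant and the
        effect would reduce to sampling covariance)."""
        from chidist.synthetic import PairedPoolSpec, RotamerMixtureSpec, \
            perturb_paired, sample_pool
        means = []
        for flip in (0.0, 0.1, 0.3):
            ds = []
            for seed in range(8):
                rng = np.random.default_rng(100 + seed)
                spec = RotamerMixtureSpec("SER", weights=(0.6, 0.25, 0.15),
                                          jitter_sd=10.0)
                pool = sample_pool(spec, 2000, rng)
                paired = perturb_paired(pool, PairedPoolSpec(
                    base=spec, flip_prob=flip, jitter_sd=10.0, n=2000), rng)
                ds.append(averaged_comparison(
                    pool.angles, paired.angles, "SER", 30.0, n_repeats=25,
                    rng=seed).mean_d)
            means.append(np.mean(ds))
        assert means[0] < means[1] < means[2]
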