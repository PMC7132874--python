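import numpy as np
import pytest
from scipy import stats

from covinform import (
    OmnibusConfig,
    OmnibusTest,
    categorize,
    chisq_score,
    decorrelate_subsample,
    dichotomize,
    null_independence_test,
    omnibus_statistic,
    trend_score,
)
from ._oracles import cochran_armitage_neglogp, omnibus_statistic_brute


class TestDichotomize:
    def test_sparse_fixture_selects_the_low_block(self):
        p = np.r_[np.full(10, 0.01), np.full(990, 0.5)]
        low = dichotomize(p, 0.01)
        assert low.sum() == 10
        assert low[:10].all()

    def test_identical_pvalues_fall_in_one_class(self):
        p = np.full(100, 0.3)
        assert dichotomize(p, 0.05).all()

    def test_uniform_fraction_matches_quantile(self, rng):
        p = rng.uniform(size=10_000)
        frac = dichotomize(p, 0.2).mean()
        assert frac == pytest.approx(0.2, abs=0.01)


class TestCategorize:
    def test_equal_splits(self):
        assert np.bincount(categorize(np.arange(32.0), 2)).tolist() == [16, 16]
        assert np.bincount(categorize(np.arange(8.0), 4)).tolist() == [2, 2, 2, 2]

    def test_heavy_ties_merge_categories(self, rng):
        x = np.r_[np.zeros(900), rng.uniform(size=100)]
        codes = categorize(x, 8)
        assert codes is not None
        assert 2 <= np.unique(codes).size < 8

    def test_constant_vector_is_untestable(self):
        assert categorize(np.ones(50), 4) is None


class TestComponentScores:
    def test_chisq_independence_scores_zero(self):
        p_bin = np.r_[np.ones(25, bool), np.zeros(25, bool),
                      np.ones(25, bool), np.zeros(25, bool)]
        x = np.r_[np.zeros(50), np.ones(50)]
        assert chisq_score(p_bin, x) == pytest.approx(0.0, abs=1e-12)

    def test_chisq_association_table_equals_twenty(self):
        # table [[30,10],[10,30]]: all expected counts 20, chi2 = 20
        p_bin = np.r_[np.ones(30, bool), np.zeros(10, bool),
                      np.ones(10, bool), np.zeros(30, bool)]
        x = np.repeat([0, 1], 40)
        expected = -stats.chi2.logsf(20.0, 1)
        assert chisq_score(p_bin, x) == pytest.approx(expected, rel=1e-10)

    def test_trend_statistic_matches_hand_derivation(self):
        # successes (10,20,30) of (40,40,40): T = 20, Var = 20, z = sqrt(20)
        p_bin = np.zeros(120, bool)
        x = np.repeat([1, 2, 3], 40)
        p_bin[:10] = True
        p_bin[40:60] = True
        p_bin[80:110] = True
        z = np.sqrt(20.0)
        expected = -(np.log(2) + stats.norm.logsf(z))
        assert trend_score(p_bin, x) == pytest.approx(expected, rel=1e-10)
        assert trend_score(p_bin, x) == pytest.approx(
            cochran_armitage_neglogp([10, 20, 30], [40, 40, 40]), rel=1e-6
        )

    def test_flat_trend_scores_zero(self):
        # balanced successes across ordered categories -> statistic 0
        p_flat = np.zeros(120, bool)
        for c in range(3):
            p_flat[40 * c : 40 * c + 20] = True
        assert trend_score(p_flat, np.repeat([1, 2, 3], 40)) == pytest.approx(0.0)

    def test_reversing_order_keeps_two_sided_trend_p(self):
        rng = np.random.default_rng(3)
        p_bin = rng.random(200) < 0.2
        x = np.repeat([1, 2, 3, 4], 50)
        assert trend_score(p_bin, x) == pytest.approx(
            trend_score(p_bin, 5 - x), rel=1e-10
        )


class TestOmnibusStatistic:
    @pytest.mark.parametrize("kind", ["continuous", "categorical"])
    def test_matches_brute_force_double_loop(self, kind, rng):
        for _ in range(3):
            p = rng.uniform(size=500) ** (1.5 if kind == "continuous" else 1.0)
            if kind == "continuous":
                x = rng.normal(size=500) + (p < 0.05)
            else:
                x = rng.integers(1, 6, size=500).astype(float)
            cfg = OmnibusConfig()
            t_obs, _ = omnibus_statistic(p, x, kind=kind, config=cfg)
            brute = omnibus_statistic_brute(
                p, x, cfg.p_cutoff_quantiles, cfg.category_counts,
                continuous=kind == "continuous",
            )
            assert t_obs == pytest.approx(brute, rel=1e-9)

    def test_log_base_change_does_not_move_the_pvalue(self, rng):
        # the max is invariant under monotone rescaling of the scores, so
        # the permutation p-value must not depend on the log base
        p = rng.uniform(size=400)
        x = rng.normal(size=400)
        res = OmnibusTest(p, x, config=OmnibusConfig(n_permutations=49, seed=5)).fit()
        t_scaled = res.t_obs / np.log(10)
        perm_scaled = res.t_perm / np.log(10)
        pval_scaled = (1 + np.sum(perm_scaled >= t_scaled)) / (1 + 49)
        assert pval_scaled == res.pval

    def test_constant_covariate_untestable(self):
        with pytest.raises(ValueError, match="untestable|constant|levels"):
            OmnibusTest(np.linspace(0.01, 1, 100), np.ones(100))


class TestOmnibusPermutation:
    def test_pvalue_formula_extremes(self, rng):
        p = np.r_[np.full(50, 1e-6), rng.uniform(0.2, 1, size=950)]
        x = np.r_[np.full(50, 5.0), rng.normal(size=950)]
        res = OmnibusTest(p, x, config=OmnibusConfig(n_permutations=99, seed=0)).fit()
        assert res.pval == pytest.approx(1.0 / 100)
        assert res.pval >= 1.0 / (res.config.n_permutations + 1)

    def test_same_seed_is_reproducible(self, rng):
        p = rng.uniform(size=300)
        x = rng.normal(size=300)
        cfg = OmnibusConfig(n_permutations=49, seed=42)
        r1 = OmnibusTest(p, x, config=cfg).fit()
        r2 = OmnibusTest(p, x, config=cfg).fit()
        assert r1.pval == r2.pval
        np.testing.assert_array_equal(r1.t_perm, r2.t_perm)

    def test_size_under_exchangeable_null(self):
        """P(pval <= 0.05) stays at or below nominal for independent data."""
        reps, hits = 120, 0
        for i in range(reps):
            r = np.random.default_rng(7000 + i)
            p = r.uniform(size=400)
            x = r.normal(size=400)
            res = OmnibusTest(
                p, x, config=OmnibusConfig(n_permutations=39, seed=i)
            ).fit()
            hits += res.pval <= 0.05
        rate = hits / reps
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)

    def test_missing_covariate_entries_are_dropped_pairwise(self, rng):
        p = rng.uniform(size=200)
        x = rng.normal(size=200)
        x[:20] = np.nan
        test = OmnibusTest(p, x)
        assert test.p.size == 180


class TestNullIndependence:
    def test_mode_is_echoed_and_null_data_not_flagged(self, rng):
        p = rng.uniform(size=2000)
        x = rng.normal(size=2000)
        res = null_independence_test(
            p, x, config=OmnibusConfig(n_permutations=99, seed=1)
        )
        assert res.config.mode == "null_independence"
        assert res.config.p_cutoff_quantiles == (0.1, 0.2, 0.4, 0.6, 0.8, 0.9)

    def test_extreme_dependence_reaches_attainable_minimum(self, rng):
        p = rng.uniform(size=2000)
        x = np.empty_like(p)
        nulls = p > 0.5
        x[nulls] = stats.rankdata(p[nulls])
        x[~nulls] = rng.normal(size=(~nulls).sum())
        res = null_independence_test(
            p, x, config=OmnibusConfig(n_permutations=99, seed=2)
        )
        assert res.pval == pytest.approx(1.0 / 100)

    def test_too_few_large_pvalues_is_an_error(self, rng):
        p = rng.uniform(0, 0.4, size=200)
        with pytest.raises(ValueError, match="above 0.5"):
            null_independence_test(p, rng.normal(size=200))


class TestDecorrelate:
    def test_iid_sequence_keeps_stride_one(self, rng):
        p = rng.uniform(size=8000)
        idx = decorrelate_subsample(p, floor=2000)
        assert idx.size == 8000

    def test_ar_series_is_thinned_until_acf_drops(self):
        rng = np.random.default_rng(0)
        m = 80_000
        z = np.empty(m)
        z[0] = rng.standard_normal()
        eps = rng.standard_normal(m)
        for i in range(1, m):
            z[i] = 0.75 * z[i - 1] + np.sqrt(1 - 0.75**2) * eps[i]
        p = stats.norm.sf(z)
        idx = decorrelate_subsample(p, threshold=0.05, floor=5000)
        assert idx.size < m
        kept = p[idx]
        kc = kept - kept.mean()
        r1 = np.sum(kc[:-1] * kc[1:]) / np.sum(kc**2)
        assert abs(r1) < 0.05

    def test_short_input_returned_unchanged(self):
        p = np.linspace(0.1, 0.9, 10)
        idx = decorrelate_subsample(p)
        np.testing.assert_array_equal(idx, np.arange(10))
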