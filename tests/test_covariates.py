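import numpy as np
import pytest

from covinform import (
    CovariateColumn,
    beta_to_m,
    build_covariate_table,
    compute_dip,
    compute_direction,
    compute_icc,
    compute_precision,
    encode_covariate,
    m_to_beta,
)
from ._oracles import dip_lp


class TestBetaToM:
    @pytest.mark.parametrize(
        "beta, expected", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)]
    )
    def test_known_values(self, beta, expected):
        assert beta_to_m(beta) == pytest.approx(expected)

    def test_antisymmetry_and_monotonicity(self, rng):
        b = rng.uniform(0.01, 0.99, size=100)
        np.testing.assert_allclose(beta_to_m(b), -beta_to_m(1 - b), atol=1e-12)
        b_sorted = np.sort(b)
        assert np.all(np.diff(beta_to_m(b_sorted)) > 0)
        np.testing.assert_allclose(m_to_beta(beta_to_m(b)), b, atol=1e-12)

    def test_boundary_is_domain_error(self):
        with pytest.raises(ValueError):
            beta_to_m(np.array([0.0, 0.5]))


class TestPrecision:
    def test_printed_formula_values(self):
        assert compute_precision(0.5, np.sqrt(0.05)) == pytest.approx(0.25)
        assert compute_precision(0.5, np.sqrt(0.125)) == pytest.approx(1.0)

    def test_variance_at_beta_bound_is_missing(self):
        assert np.isnan(compute_precision(0.5, 0.5))


class TestDip:
    def test_balanced_two_point_sample_reaches_maximum(self):
        x = np.r_[np.zeros(50), np.ones(50)]
        assert compute_dip(x) == pytest.approx(0.25, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=40)
        assert compute_dip(10 * x + 3) == pytest.approx(compute_dip(x), abs=1e-12)

    def test_uniform_sample_has_small_dip(self):
        x = np.random.default_rng(1).uniform(size=10_000)
        assert 0 < compute_dip(x) < 0.01

    def test_requires_at_least_four_values(self):
        with pytest.raises(ValueError):
            compute_dip([1.0, 2.0, 3.0])

    @pytest.mark.parametrize("trial", range(12))
    def test_agrees_with_unimodal_envelope_lp_oracle(self, trial):
        """The implementation must match direct LP minimization over
        piecewise-linear unimodal ecdf envelopes on small samples."""
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(6, 51))
        kind = trial % 4
        if kind == 0:
            x = rng.uniform(size=n)
        elif kind == 1:
            x = rng.integers(0, 4, size=n).astype(float)
        elif kind == 2:
            x = np.r_[rng.normal(-2, 0.4, n // 2), rng.normal(2, 0.4, n - n // 2)]
        else:
            x = rng.exponential(size=n)
        oracle = dip_lp(x)
        # the estimator floors at 1/(2n), the attainable minimum
        expected = max(oracle, 1.0 / (2 * n))
        assert compute_dip(x) == pytest.approx(expected, abs=1e-9)


class TestDirection:
    def test_perfectly_aligned_and_opposed_features(self):
        pheno = np.array([0.0, 1.0, 2.0, 3.0])
        m_mat = np.vstack([pheno, -pheno, np.zeros(4)])
        out = compute_direction(m_mat, pheno)
        assert out.tolist() == ["positive", "negative", "positive"]

    def test_constant_phenotype_is_an_error(self):
        with pytest.raises(ValueError):
            compute_direction(np.ones((2, 3)), np.ones(3))


class TestIcc:
    def test_identical_replicates_give_one(self):
        assert compute_icc([1, 1, 3, 3], ["A", "A", "B", "B"]) == pytest.approx(1.0)

    def test_between_group_variance_zero_gives_minus_one(self):
        # one-way ANOVA by hand: MSB = 0, MSW = 2, k0 = 2 -> ICC = -1
        assert compute_icc([1, 3, 1, 3], ["A", "A", "B", "B"]) == pytest.approx(-1.0)

    def test_no_variance_is_missing(self):
        assert np.isnan(compute_icc([0, 0, 0, 0], ["A", "A", "B", "B"]))

    def test_all_singletons_rejected(self):
        with pytest.raises(ValueError):
            compute_icc([1, 2, 3], ["A", "B", "C"])


class TestBuildCovariateTable:
    def test_plain_study_emits_the_seven_statistical_covariates(self, small_study):
        small_study.replicate_group = None
        cols = build_covariate_table(small_study)
        assert [c.name for c in cols] == [
            "mean", "sd.b", "sd.m", "mad", "dip", "precision", "direction",
        ]
        kinds = {c.name: c.kind for c in cols}
        assert kinds["direction"] == "categorical"
        assert all(kinds[n] == "continuous" for n in ("mean", "sd.b", "dip"))

    def test_replicates_add_icc_columns(self, small_study):
        names = [c.name for c in build_covariate_table(small_study)]
        assert "icc.b" in names and "icc.m" in names

    def test_mad_two_point_convention(self, rng):
        # {a,a,b,b}: median-centred absolute deviations all |a-b|/2
        from covinform.io import MethylationStudy

        a, b = 0.3, 0.5
        study = MethylationStudy(
            beta=np.tile([a, a, b, b], (4, 1)),
            feature_ids=[f"f{i}" for i in range(4)],
            sample_ids=list("wxyz"),
            phenotype=[0, 0, 1, 1],
        )
        cols = {c.name: c for c in build_covariate_table(study)}
        np.testing.assert_allclose(
            cols["mad"].x, 1.4826022185056018 * abs(a - b) / 2, rtol=1e-6
        )

    def test_summaries_are_sample_permutation_invariant(self, small_study, rng):
        small_study.replicate_group = None
        cols = {c.name: c.x for c in build_covariate_table(small_study)}
        perm = rng.permutation(small_study.n_samples)
        shuffled = type(small_study)(
            beta=small_study.beta[:, perm],
            feature_ids=small_study.feature_ids,
            sample_ids=small_study.sample_ids[perm],
            phenotype=small_study.phenotype,  # NOT permuted: direction may flip
        )
        cols_shuffled = {c.name: c.x for c in build_covariate_table(shuffled)}
        for name in ("mean", "sd.b", "sd.m", "mad", "dip", "precision"):
            np.testing.assert_allclose(cols[name], cols_shuffled[name], atol=1e-12)


class TestEncodeCovariate:
    def test_continuous_gets_six_spline_columns(self, rng):
        col = CovariateColumn(rng.normal(size=1000), "continuous", "mean")
        basis = encode_covariate(col)
        assert basis.matrix.shape == (1000, 6)
        assert np.linalg.matrix_rank(basis.matrix) == 6

    def test_binary_category_gets_single_indicator(self):
        col = CovariateColumn(np.array(["yes", "no", "yes", "no"]), "categorical", "dhs")
        basis = encode_covariate(col)
        assert basis.matrix.shape == (4, 1)
        np.testing.assert_array_equal(basis.matrix[:, 0], [1, 0, 1, 0])

    def test_constant_column_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            encode_covariate(CovariateColumn(np.ones(10), "continuous", "z"))

    def test_few_distinct_values_degrade_df(self, caplog):
        x = np.tile([1.0, 2.0, 3.0], 10)
        with caplog.at_level("WARNING"):
            basis = encode_covariate(CovariateColumn(x, "continuous", "z"))
        assert basis.matrix.shape[1] < 6
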