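import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from mitomr.stats import (ConvergenceError, bonferroni_threshold, fit_linear,
                          fit_logistic, inverse_rank_normal,
                          mahalanobis_distances, meta_fixed_ivw,
                          meta_random_dl, qvalues_bh_storey, rubin_combine)


# ---------------------------------------------------------------------------
# inverse rank normal


class TestInverseRankNormal:
    def test_three_point_quantiles(self):
        out = inverse_rank_normal([10, 20, 30])
        expected = sps.norm.ppf([1 / 6, 3 / 6, 5 / 6])
        np.testing.assert_allclose(out, expected, atol=1e-10)
        np.testing.assert_allclose(out, [-0.9674, 0.0, 0.9674], atol=1e-4)

    def test_ties_map_to_average_rank_quantile(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = inverse_rank_normal([5.0, 5.0])
        np.testing.assert_allclose(out, [0.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(inverse_rank_normal([5.0, 5.0, 9.0]),
                                   [sps.norm.ppf(1.0 / 3)] * 2
                                   + [sps.norm.ppf(5.0 / 6)])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=40,
                    unique=True))
    def test_tie_free_sum_zero_and_monotone(self, vals):
        out = inverse_rank_normal(vals)
        assert abs(out.sum()) < 1e-8
        order_in = np.argsort(vals)
        assert np.all(np.diff(out[order_in]) > 0)

    def test_degenerate_inputs_signaled(self):
        with pytest.raises(ValueError):
            inverse_rank_normal([1.0])
        with pytest.warns(UserWarning, match="degenerate"):
            inverse_rank_normal([2.0, 2.0, 2.0])


# ---------------------------------------------------------------------------
# linear / logistic fits


class TestFitLinear:
    def test_exact_column_recovery(self, rng):
        X = np.column_stack([np.ones(30), rng.normal(size=30),
                             rng.normal(size=30)])
        fit = fit_linear(X[:, 1], X)
        np.testing.assert_allclose(fit.coefficients, [0, 1, 0], atol=1e-10)
        np.testing.assert_allclose(fit.residuals, 0, atol=1e-10)

    def test_intercept_only_gives_mean(self, rng):
        y = rng.normal(2.0, 1.0, size=25)
        fit = fit_linear(y, np.ones((25, 1)))
        assert fit.coefficients[0] == pytest.approx(y.mean(), abs=1e-12)

    def test_matches_normal_equations_and_statsmodels(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        beta_ne = np.linalg.solve(X.T @ X, X.T @ y)
        fit = fit_linear(y, X)
        np.testing.assert_allclose(fit.coefficients, beta_ne, atol=1e-10)
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.standard_errors, ref.bse, rtol=1e-8)
        np.testing.assert_allclose(fit.p_values, ref.pvalues, rtol=1e-8)
        infl = ref.get_influence()
        np.testing.assert_allclose(fit.leverage, infl.hat_matrix_diag,
                                   atol=1e-10)

    def test_leverage_and_orthogonality_invariants(self, rng):
        X = np.column_stack([np.ones(40), rng.normal(size=(40, 3))])
        y = rng.normal(size=40)
        fit = fit_linear(y, X)
        assert np.all((fit.leverage >= 0) & (fit.leverage <= 1))
        assert fit.leverage.sum() == pytest.approx(X.shape[1], abs=1e-8)
        np.testing.assert_allclose(X.T @ fit.residuals, 0, atol=1e-8)

    def test_error_conditions(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(np.linalg.LinAlgError):
            fit_linear(rng.normal(size=10), np.column_stack([X, X[:, 0]]))
        with pytest.raises(ValueError):
            fit_linear(rng.normal(size=3), rng.normal(size=(3, 3)))


class TestFitLogistic:
    def test_two_by_two_log_odds_ratio(self):
        # cells: exposed 10 cases / 20 controls, unexposed 30 / 40
        y = np.r_[np.ones(10), np.zeros(20), np.ones(30), np.zeros(40)]
        x = np.r_[np.ones(30), np.zeros(70)]
        fit = fit_logistic(y, np.column_stack([np.ones(100), x]))
        assert fit.coefficients[1] == pytest.approx(
            np.log(10 * 40 / (20 * 30)), abs=1e-6)
        assert fit.coefficients[1] == pytest.approx(-0.4055, abs=1e-4)

    def test_equal_rates_give_zero_slope(self):
        y = np.r_[np.ones(5), np.zeros(5), np.ones(10), np.zeros(10)]
        x = np.r_[np.ones(10), np.zeros(20)]
        fit = fit_logistic(y, np.column_stack([np.ones(30), x]))
        assert abs(fit.coefficients[1]) < 1e-8

    def test_matches_statsmodels(self, rng):
        X = np.column_stack([np.ones(200), rng.normal(size=(200, 2))])
        eta = X @ [0.2, 0.8, -0.5]
        y = (rng.random(200) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(y, X)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.standard_errors, ref.bse, rtol=1e-5)

    def test_perfect_separation_flagged(self):
        x = np.r_[np.linspace(-2, -1, 10), np.linspace(1, 2, 10)]
        y = (x > 0).astype(float)
        with pytest.raises(ConvergenceError):
            fit_logistic(y, np.column_stack([np.ones(20), x]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones(10), np.ones((10, 1)))


# ---------------------------------------------------------------------------
# Rubin's rules


class TestRubinCombine:
    def test_no_between_variance(self):
        beta, se, df, p = rubin_combine([0.5] * 4, [0.09] * 4)
        assert beta == 0.5
        assert se == pytest.approx(np.sqrt(0.09), abs=1e-12)

    def test_thousand_imputations_use_998_df(self):
        est = np.linspace(0.9, 1.1, 1000)
        _, _, df, _ = rubin_combine(est, np.full(1000, 0.01))
        assert df == 998

    def test_hand_computed_three_imputation_oracle(self):
        beta, se, df, _ = rubin_combine([1.0, 1.2, 1.4], [0.04] * 3)
        assert beta == pytest.approx(1.2)
        assert se**2 == pytest.approx(0.04 + (4 / 3) * 0.04, rel=1e-10)
        assert se == pytest.approx(0.30551, abs=1e-5)
        assert df == 1

    def test_barnard_rubin_option(self):
        _, _, df, _ = rubin_combine([1.0, 1.2], [0.04, 0.04],
                                    df_method="barnard_rubin")
        assert df > 0

    def test_errors(self):
        with pytest.raises(ValueError):
            rubin_combine([1.0], [0.1])
        with pytest.raises(ValueError):
            rubin_combine([1.0, 2.0], [0.1, 0.0])


# ---------------------------------------------------------------------------
# meta-analysis


class TestMeta:
    def test_ivw_weighted_example(self):
        m = meta_fixed_ivw([0.1, 0.3], [0.05, 0.1])  # weights 400 and 100
        assert m.beta == pytest.approx(0.14, rel=1e-12)
        assert m.se == pytest.approx(np.sqrt(1 / 500), rel=1e-12)
        assert m.se == pytest.approx(0.04472, abs=1e-5)

    def test_single_study_passthrough(self):
        m = meta_fixed_ivw([0.25], [0.07])
        assert (m.beta, m.se) == (0.25, 0.07)

    def test_two_identical_studies_halve_variance(self):
        m = meta_fixed_ivw([0.2, 0.2], [0.1, 0.1])
        assert m.beta == pytest.approx(0.2)
        assert m.se == pytest.approx(0.1 / np.sqrt(2))

    def test_dl_homogeneous_reduces_to_ivw(self):
        fixed = meta_fixed_ivw([0.2, 0.21, 0.19], [0.1, 0.1, 0.1])
        rand = meta_random_dl([0.2, 0.21, 0.19], [0.1, 0.1, 0.1])
        assert rand.tau2 == 0.0
        assert rand.beta == pytest.approx(fixed.beta)
        assert rand.se == pytest.approx(fixed.se)

    def test_dl_hand_computed_oracle(self):
        # w = 100 each; Q = 50; tau2 = (50-1)/(200-100) = 0.49;
        # reweight 1/(0.01+0.49) = 2 -> se = sqrt(1/4)
        m = meta_random_dl([0.0, 1.0], [0.1, 0.1])
        assert m.tau2 == pytest.approx(0.49, rel=1e-12)
        assert m.beta == pytest.approx(0.5)
        assert m.se == pytest.approx(0.5, rel=1e-12)

    def test_dl_equal_betas_passthrough(self):
        m = meta_random_dl([0.3, 0.3, 0.3], [0.1, 0.2, 0.3])
        assert m.beta == pytest.approx(0.3)


# ---------------------------------------------------------------------------
# multiplicity


class TestQValues:
    def test_all_unit_pvalues(self):
        qt = qvalues_bh_storey(np.ones(50))
        assert qt.pi0 == 1.0
        np.testing.assert_allclose(qt.q_values, 1.0)

    def test_bh_reduction_at_pi0_one(self):
        qt = qvalues_bh_storey([0.01, 0.02, 0.03, 0.04], pi0=1.0)
        np.testing.assert_allclose(qt.q_values, 0.04, rtol=1e-12)

    def test_permutation_invariance(self, rng):
        p = rng.random(60)
        perm = rng.permutation(60)
        q1 = qvalues_bh_storey(p, pi0=1.0).q_values
        q2 = qvalues_bh_storey(p[perm], pi0=1.0).q_values
        np.testing.assert_allclose(q1[perm], q2)

    def test_uniform_null_pi0_near_one(self):
        p = np.random.default_rng(2024).random(1000)
        qt = qvalues_bh_storey(p)
        assert 0.8 <= qt.pi0 <= 1.0

    def test_q_monotone_in_p(self, rng):
        p = rng.random(40)
        qt = qvalues_bh_storey(p)
        order = np.argsort(p)
        assert np.all(np.diff(qt.q_values[order]) >= -1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            qvalues_bh_storey([0.5, 1.2])


class TestBonferroni:
    @pytest.mark.parametrize("n,alpha,expected", [
        (23105, 0.05, 2.164e-6),
        (1, 0.05, 0.05),
        (100, 0.05, 5e-4),
    ])
    def test_threshold(self, n, alpha, expected):
        assert bonferroni_threshold(n, alpha) == pytest.approx(expected,
                                                               rel=5e-4)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0, 0.05)


# ---------------------------------------------------------------------------
# Mahalanobis


class TestMahalanobis:
    def test_center_gives_zero(self):
        d = mahalanobis_distances([[1.0, 2.0]], [1.0, 2.0], np.eye(2))
        assert d[0] == 0.0

    def test_identity_covariance_is_euclidean(self, rng):
        X = rng.normal(size=(10, 3))
        d = mahalanobis_distances(X, np.zeros(3), np.eye(3))
        np.testing.assert_allclose(d, np.linalg.norm(X, axis=1), rtol=1e-12)

    def test_anisotropic_hand_example(self):
        d = mahalanobis_distances([[2.0, 1.0]], [0.0, 0.0],
                                  [[2.0, 0.0], [0.0, 0.5]])
        assert d[0] == pytest.approx(2.0, rel=1e-12)

    def test_singular_covariance_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            mahalanobis_distances([[1.0, 1.0]], [0, 0], np.ones((2, 2)))
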