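import numpy as np
import pandas as pd
import pytest

from mitomr.mr import (MrConfig, MrDataset, build_instrument,
                       classify_for_causality, partition_covariates,
                       posthoc_outlier_rerun, run_mr)
from mitomr.mr import test_causality as causality_test
from mitomr.simulate import CohortConfig, simulate_cohort, simulate_genotypes
from mitomr.stats import PenaltySpec


# ---------------------------------------------------------------------------
# covariate screening


class TestPartitionCovariates:
    def _planted(self, seed=0, n=3000):
        g = np.random.default_rng(seed)
        W = pd.DataFrame({"wy": g.normal(size=n), "wx": g.normal(size=n),
                          "n1": g.normal(size=n), "n2": g.normal(size=n)})
        X = 0.5 * W["wx"] + g.normal(size=n)
        Y = 0.5 * W["wy"] + g.normal(size=n)
        return W, X.to_numpy(), Y.to_numpy()

    def test_planted_covariates_recovered(self):
        W, X, Y = self._planted()
        part = partition_covariates(W, X, Y)
        assert part.set_A == ["wy"]
        assert part.set_B == ["wx"]

    def test_y_association_takes_precedence(self):
        g = np.random.default_rng(1)
        n = 3000
        wboth = g.normal(size=n)
        W = pd.DataFrame({"wboth": wboth, "null": g.normal(size=n)})
        X = 0.5 * wboth + g.normal(size=n)
        Y = 0.5 * wboth + g.normal(size=n)
        part = partition_covariates(W, X, Y)
        assert part.set_A == ["wboth"] and part.set_B == []

    def test_all_null_covariates_yield_empty_sets(self):
        g = np.random.default_rng(2)
        n = 5000
        W = pd.DataFrame(g.normal(size=(n, 8)),
                         columns=[f"w{i}" for i in range(8)])
        part = partition_covariates(W, g.normal(size=n), g.normal(size=n),
                                    alpha_screen=0.001)
        assert part.set_A == [] and part.set_B == []

    def test_constant_column_dropped_with_warning(self):
        W, X, Y = self._planted(seed=3)
        W["const"] = 1.0
        with pytest.warns(UserWarning, match="const"):
            part = partition_covariates(W, X, Y)
        assert "const" not in part.set_A + part.set_B


class TestClassifyForCausality:
    def test_null_covariates_all_in_set_one(self):
        g = np.random.default_rng(4)
        n = 5000
        W = pd.DataFrame(g.normal(size=(n, 6)),
                         columns=[f"w{i}" for i in range(6)])
        sets = classify_for_causality(W, g.normal(size=n), g.normal(size=n),
                                      alpha_screen=0.001)
        assert sets.set_I == list(W.columns)
        assert sets.adjusted == []

    def test_double_associated_covariate_adjusted(self):
        g = np.random.default_rng(5)
        n = 2000
        w = g.normal(size=n)
        Z = 0.5 * w + g.normal(size=n)
        Y = 0.5 * w + g.normal(size=n)
        W = pd.DataFrame({"w": w, "null": g.normal(size=n)})
        sets = classify_for_causality(W, Z, Y)
        assert "w" in sets.set_II
        assert "w" in sets.adjusted

    def test_sets_partition_the_covariates(self):
        g = np.random.default_rng(6)
        n = 1500
        W = pd.DataFrame(g.normal(size=(n, 5)),
                         columns=[f"w{i}" for i in range(5)])
        sets = classify_for_causality(W, g.normal(size=n), g.normal(size=n),
                                      alpha_screen=0.05)
        all_members = sets.set_I + sets.set_II + sets.set_III + sets.set_IV
        assert sorted(all_members) == sorted(W.columns)


# ---------------------------------------------------------------------------
# instrument construction


class TestBuildInstrument:
    def test_full_shrinkage_zeroes_the_instrument(self, rng):
        G = rng.normal(size=(100, 10))
        X = rng.normal(size=100)
        inst = build_instrument(X, G, None,
                                PenaltySpec(kind="L1", lam=1e9), seed=0)
        np.testing.assert_allclose(inst.beta_G_per_fold, 0.0)
        np.testing.assert_allclose(inst.Z, 0.0)

    def test_every_sample_in_exactly_one_fold(self, rng):
        G = rng.normal(size=(103, 5))
        inst = build_instrument(rng.normal(size=103), G, None,
                                PenaltySpec(kind="L2", lam=10.0), K=5, seed=1)
        counts = np.bincount(inst.fold_assignment, minlength=5)
        assert counts.sum() == 103 and counts.min() >= 20

    def test_z_uses_only_out_of_fold_weights(self, rng):
        G = rng.normal(size=(80, 6))
        X = rng.normal(size=80)
        inst = build_instrument(X, G, None,
                                PenaltySpec(kind="L2", lam=5.0), seed=2)
        manual = np.einsum("ij,ij->i", G,
                           inst.beta_G_per_fold[inst.fold_assignment])
        np.testing.assert_allclose(inst.Z, manual, atol=1e-12)

    def test_out_of_fold_prediction_decorrelates_from_noise(self):
        # in-fold (overfit) weights correlate with the exposure noise;
        # held-out weights must not
        cfg = CohortConfig(n_samples=400, n_variants=100, h2_instrument=0.3,
                           confounder_strengths=(0.0, 0.0), seed=55)
        coh = simulate_cohort(cfg)
        G = coh.dosages
        gs = (G - G.mean(0)) / G.std(0)
        signal = gs @ np.array(coh.truth["beta_g"])
        eps = coh.X - coh.config.depth_params.mtcn_scale * signal
        spec = PenaltySpec(kind="L2", lam=1e-6)
        inst = build_instrument(coh.X, G, None, spec, seed=3)
        beta_in, _ = __import__("mitomr").stats.fit_penalized(
            coh.X, G, np.ones((400, 1)), spec)
        z_in = G @ beta_in
        assert abs(np.corrcoef(inst.Z, eps)[0, 1]) < \
            abs(np.corrcoef(z_in, eps)[0, 1])

    def test_cv_instrument_tracks_true_polygenic_score(self):
        cfg = CohortConfig(n_samples=4000, n_variants=100, h2_instrument=0.3,
                           seed=66)
        coh = simulate_cohort(cfg)
        gs = (coh.dosages - coh.dosages.mean(0)) / coh.dosages.std(0)
        signal = gs @ np.array(coh.truth["beta_g"])
        inst = build_instrument(coh.X, coh.dosages, None,
                                PenaltySpec(kind="L2",
                                            selection="cross_validated"),
                                seed=4)
        assert np.corrcoef(inst.Z, signal)[0, 1] > 0.5

    def test_invalid_folds_rejected(self, rng):
        with pytest.raises(ValueError):
            build_instrument(rng.normal(size=10), rng.normal(size=(10, 2)),
                             None, PenaltySpec(), K=11)


# ---------------------------------------------------------------------------
# causality test


class TestCausality:
    def test_known_effect_recovered(self, rng):
        Z = rng.normal(size=2000)
        Y = 0.2 * Z + rng.normal(size=2000)
        est, se = causality_test(Y, Z)
        assert abs(est - 0.2) < 2 * se

    def test_orthogonal_covariate_leaves_estimate_unchanged(self, rng):
        n = 500
        Z = rng.normal(size=n)
        Y = 0.3 * Z + rng.normal(size=n)
        est0, _ = causality_test(Y, Z)
        # residualize a random vector on [1, Z, Y] for exact orthogonality
        M = np.column_stack([np.ones(n), Z, Y])
        v = rng.normal(size=n)
        v -= M @ np.linalg.lstsq(M, v, rcond=None)[0]
        est1, _ = causality_test(Y, Z, v)
        assert abs(est1 - est0) < 1e-10

    def test_degenerate_instrument_rejected(self, rng):
        with pytest.raises(ValueError):
            causality_test(rng.normal(size=50), np.zeros(50))


# ---------------------------------------------------------------------------
# full pipeline


class TestRunMr:
    def test_single_dataset_meta_equals_pooled(self):
        coh = simulate_cohort(CohortConfig(n_samples=800, n_variants=30,
                                           seed=77))
        ds = MrDataset.from_cohort(coh)
        res = run_mr(ds, MrConfig(penalties=("L2",), m_imputations=3,
                                  mi_learner="gaussian", mi_maxit=3, seed=8))
        r = res["L2"]
        beta, se, _, _ = r.pooled["synthetic"]
        assert r.meta.beta == pytest.approx(beta)
        assert r.meta.se == pytest.approx(se)
        assert r.meta.k == 1

    def test_pooled_se_dominates_mean_within_se(self):
        coh = simulate_cohort(CohortConfig(n_samples=800, n_variants=30,
                                           seed=78))
        res = run_mr(MrDataset.from_cohort(coh),
                     MrConfig(penalties=("L2",), m_imputations=4,
                              mi_learner="gaussian", mi_maxit=3, seed=9))
        r = res["L2"]
        ses = [s for _, s in r.per_imputation["synthetic"]]
        assert r.pooled["synthetic"][1] >= np.mean(ses) - 1e-12

    def test_exclusion_restriction_proxy_under_full_null(self):
        cfg = CohortConfig(n_samples=2000, n_variants=50, theta=0.0,
                           confounder_strengths=(0.0, 0.0),
                           missing_rate=0.0, seed=79)
        coh = simulate_cohort(cfg)
        inst = build_instrument(coh.X, coh.dosages, None,
                                PenaltySpec(kind="L2",
                                            selection="cross_validated"),
                                seed=10)
        assert abs(np.corrcoef(inst.Z, coh.Y)[0, 1]) < 3.5 / np.sqrt(2000)

    def test_fewer_than_two_imputations_rejected(self):
        coh = simulate_cohort(CohortConfig(n_samples=100, n_variants=5,
                                           seed=80))
        with pytest.raises(ValueError):
            run_mr(MrDataset.from_cohort(coh), MrConfig(m_imputations=1))


class TestPosthocRerun:
    def _dataset(self, seed=81, n=600):
        cfg = CohortConfig(n_samples=n, n_variants=20, missing_rate=0.0,
                           seed=seed)
        return MrDataset.from_cohort(simulate_cohort(cfg))

    def test_planted_outliers_recovered(self):
        ds = self._dataset()
        # extreme covariate (leverage) plus gross response error (residual)
        ds.W.loc[:4, "wa1"] = 8.0
        ds.Y[:5] += 30.0
        cfg = MrConfig(penalties=("L2",), m_imputations=2,
                       mi_learner="gaussian", mi_maxit=2,
                       remove_outliers=False, seed=11)
        res = run_mr(ds, cfg)
        rerun, excluded = posthoc_outlier_rerun(res, ds, cfg)
        planted = set(np.asarray(ds.sample_ids)[:5])
        assert planted.issubset(set(excluded))
        assert "L2" in rerun

    def test_no_flags_means_no_rerun(self):
        ds = self._dataset(seed=82)
        cfg = MrConfig(penalties=("L2",), m_imputations=2,
                       mi_learner="gaussian", mi_maxit=2, seed=12)
        res = run_mr(ds, cfg)
        for r in res.values():   # simulate a clean causality regression
            r.outlier_candidates = {k: set() for k in r.outlier_candidates}
        rerun, excluded = posthoc_outlier_rerun(res, ds, cfg)
        assert excluded == []
        assert rerun is res
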