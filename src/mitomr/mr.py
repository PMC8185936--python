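"""Penalized-instrument Mendelian randomization of an exposure on an outcome.

The procedure tests whether X (here ln MT-CN) is causal for Y (ln fasting
insulin) using a genetic instrument Z built from many variants at once:

1. Covariate partitioning: columns of the covariate matrix W associated
   with Y form set A; columns associated with X conditional on A form
   set B.  A and B are adjusted, unpenalized, in the instrument-building
   regression so that Z is built orthogonal to them.
2. Instrument construction: X is regressed on the genotype matrix G with
   an L1 or L2 penalty (free block A ∪ B), in K=5 folds; each sample's
   instrument value Z_i = G_i · beta^(−fold(i)) uses only weights fit with
   that sample held out, preventing overfitting-induced correlation
   between Z and the noise in X.
3. Causality-test adjustment: covariates are classified by first-order
   association with Z and with Y into sets I (neither, never adjusted),
   II (both), III (Z only) and IV (Y only); II ∪ III ∪ IV are adjusted in
   the regression of Y on Z.
4. Missing phenotypes are multiply imputed (chained regression trees) and
   the whole chain is repeated inside every imputation; per-imputation
   estimates are pooled with Rubin's rules and referred to a t
   distribution with m − 2 degrees of freedom.
5. Datasets are combined by fixed-effect inverse-variance weighted
   meta-analysis with a Z test.

Outliers are handled in two stages: multivariate (PCA + Mahalanobis)
trimming of the quantitative-trait matrix before the analysis, and a
post hoc rerun excluding every sample that was ever among the ten
highest-leverage points with standardized residual above one in any
imputation's causality regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .impute import mi_impute
from .simulate import SyntheticCohort
from .stats import (PenaltySpec, fit_linear, fit_penalized, meta_fixed_ivw,
                    rubin_combine, mahalanobis_distances, MetaEstimate)
from ._penalized import select_lambda_cv

__all__ = [
    "CovariatePartition",
    "CausalityAdjustmentSets",
    "InstrumentModel",
    "MrDataset",
    "MrConfig",
    "MrResult",
    "partition_covariates",
    "build_instrument",
    "classify_for_causality",
    "test_causality",
    "run_mr",
    "posthoc_outlier_rerun",
]


# ---------------------------------------------------------------------------
# covariate screening


@dataclass
class CovariatePartition:
    set_A: list
    set_B: list
    alpha_screen: float


@dataclass
class CausalityAdjustmentSets:
    set_I: list    # associated with neither Z nor Y
    set_II: list   # associated with both
    set_III: list  # Z only
    set_IV: list   # Y only

    @property
    def adjusted(self) -> list:
        return [*self.set_II, *self.set_III, *self.set_IV]


def _screen_columns(W: pd.DataFrame):
    keep = []
    for col in W.columns:
        v = W[col].to_numpy(dtype=float)
        if np.nanstd(v) == 0:
            warnings.warn(f"dropping constant covariate {col!r}")
            continue
        keep.append(col)
    if not keep:
        raise ValueError("covariate matrix has no usable columns")
    return keep


def _marginal_p(target: np.ndarray, covariate: np.ndarray,
                extra: np.ndarray | None = None) -> float:
    n = target.size
    cols = [np.ones(n), covariate]
    if extra is not None and extra.size:
        cols.insert(1, extra)
    design = np.column_stack(cols)
    return float(fit_linear(target, design).p_values[-1])


def partition_covariates(W: pd.DataFrame, X, Y,
                         alpha_screen: float | None = None) -> CovariatePartition:
    """Split covariates into set A (Y-associated) and set B (X-associated
    conditional on A); A takes precedence.  Screening uses complete-case
    rows and marginal linear regressions at ``alpha_screen`` (default the
    Bonferroni level 0.05 / #covariates)."""
    X = np.asarray(X, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float).ravel()
    cols = _screen_columns(W)
    if alpha_screen is None:
        alpha_screen = 0.05 / len(cols)
    Wv = W[cols].to_numpy(dtype=float)
    cc = np.isfinite(X) & np.isfinite(Y) & np.all(np.isfinite(Wv), axis=1)
    Xc, Yc, Wc = X[cc], Y[cc], Wv[cc]
    set_A = [c for i, c in enumerate(cols)
             if _marginal_p(Yc, Wc[:, i]) < alpha_screen]
    A_idx = [cols.index(c) for c in set_A]
    extra = Wc[:, A_idx] if A_idx else None
    set_B = [c for i, c in enumerate(cols)
             if c not in set_A and _marginal_p(Xc, Wc[:, i], extra) < alpha_screen]
    return CovariatePartition(set_A, set_B, alpha_screen)


def classify_for_causality(W: pd.DataFrame, Z, Y,
                           alpha_screen: float | None = None
                           ) -> CausalityAdjustmentSets:
    """Classify covariates by first-order association with Z and with Y.

    Set I: neither (left out of the causality test); II: both; III: Z
    only; IV: Y only.  II ∪ III ∪ IV form the adjusted set.
    """
    Z = np.asarray(Z, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float).ravel()
    cols = _screen_columns(W)
    if alpha_screen is None:
        alpha_screen = 0.05 / len(cols)
    Wv = W[cols].to_numpy(dtype=float)
    cc = np.isfinite(Z) & np.isfinite(Y) & np.all(np.isfinite(Wv), axis=1)
    Zc, Yc, Wc = Z[cc], Y[cc], Wv[cc]
    sets = {"I": [], "II": [], "III": [], "IV": []}
    for i, c in enumerate(cols):
        with_z = _marginal_p(Zc, Wc[:, i]) < alpha_screen
        with_y = _marginal_p(Yc, Wc[:, i]) < alpha_screen
        key = {(True, True): "II", (True, False): "III",
               (False, True): "IV", (False, False): "I"}[(with_z, with_y)]
        sets[key].append(c)
    return CausalityAdjustmentSets(sets["I"], sets["II"], sets["III"], sets["IV"])


# ---------------------------------------------------------------------------
# instrument construction


@dataclass
class InstrumentModel:
    fold_assignment: np.ndarray
    beta_G_per_fold: np.ndarray     # K x m
    beta_G_bar: np.ndarray          # averaged weights
    Z: np.ndarray                   # out-of-fold instrument values
    penalty: PenaltySpec
    lambdas: np.ndarray             # per-fold lambda actually used
    adjusted_covariates: list


def build_instrument(X, G, W_AB, penalty: PenaltySpec, K: int = 5,
                     seed=0) -> InstrumentModel:
    """Out-of-fold penalized instrument.

    Samples are partitioned into K folds by a seeded shuffle.  For each
    fold j the penalized regression of X on G (free block: intercept plus
    W_AB) is fit on the samples *not* in j; the held-out samples receive
    Z_i = G_i · beta^(−j).  With ``penalty.selection == "cross_validated"``
    lambda is chosen per fold by inner 5-fold cross-validation with the
    one-standard-error rule.
    """
    X = np.asarray(X, dtype=float).ravel()
    G = np.asarray(G, dtype=float)
    n = X.size
    if G.ndim != 2 or G.shape[0] != n or G.shape[1] == 0:
        raise ValueError("G must be a nonempty n x m matrix")
    if K < 2 or K > n:
        raise ValueError("fold count must satisfy 2 <= K <= n")
    if W_AB is None:
        W_AB = np.empty((n, 0))
    W_AB = np.asarray(W_AB, dtype=float)
    if W_AB.ndim == 1:
        W_AB = W_AB[:, None]
    if n <= W_AB.shape[1] + 1:
        raise ValueError("need more samples than free-block columns")
    F = np.column_stack([np.ones(n), W_AB])

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[perm] = np.arange(n) % K

    m = G.shape[1]
    betas = np.empty((K, m))
    lambdas = np.empty(K)
    Z = np.empty(n)
    for j in range(K):
        tr = fold_of != j
        if penalty.selection == "cross_validated":
            lam = select_lambda_cv(X[tr], G[tr], F[tr], penalty.kind,
                                   n_folds=5, rng=rng)
        else:
            lam = penalty.lam
        spec = PenaltySpec(kind=penalty.kind, lam=lam, selection="fixed")
        beta, _ = fit_penalized(X[tr], G[tr], F[tr], spec)
        betas[j] = beta
        lambdas[j] = lam
        Z[~tr] = G[~tr] @ beta
    return InstrumentModel(fold_of, betas, betas.mean(axis=0), Z, penalty,
                           lambdas, [])


# ---------------------------------------------------------------------------
# causality test


def _causality_fit(Y, Z, adjust):
    Y = np.asarray(Y, dtype=float).ravel()
    Z = np.asarray(Z, dtype=float).ravel()
    if Z.std() == 0:
        raise ValueError("instrument is degenerate (zero variance)")
    cols = [np.ones(Y.size), Z]
    if adjust is not None:
        A = np.asarray(adjust, dtype=float)
        if A.ndim == 1:
            A = A[:, None]
        if A.shape[1]:
            cols.append(A)
    fit = fit_linear(Y, np.column_stack(cols))
    return fit


def test_causality(Y, Z, adjust=None):
    """OLS of Y on Z plus adjusted covariates; returns the Z coefficient
    and its standard error."""
    fit = _causality_fit(Y, Z, adjust)
    return float(fit.coefficients[1]), float(fit.standard_errors[1])


# ---------------------------------------------------------------------------
# datasets and the full pipeline


@dataclass
class MrDataset:
    """One cohort's inputs: exposure, genotypes, covariates, outcome."""

    name: str
    X: np.ndarray                 # ln(raw MT-CN)
    Y: np.ndarray                 # ln(insulin)
    G: np.ndarray                 # dosage matrix
    W: pd.DataFrame
    missing_mask: pd.DataFrame | None = None   # over Y and W columns
    sample_ids: list | None = None
    age: np.ndarray | None = None              # MAR drivers; joined to the
    sex: np.ndarray | None = None              # imputation model when present

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float).ravel()
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        self.G = np.asarray(self.G, dtype=float)
        if self.sample_ids is None:
            self.sample_ids = [f"{self.name}:{i}" for i in range(self.X.size)]

    @classmethod
    def from_cohort(cls, cohort: SyntheticCohort, name: str = "synthetic"
                    ) -> "MrDataset":
        return cls(name=name, X=cohort.X.copy(), Y=cohort.Y.copy(),
                   G=cohort.dosages.copy(), W=cohort.W.copy(),
                   missing_mask=cohort.missing_mask.copy(),
                   sample_ids=list(cohort.sample_ids),
                   age=cohort.age.copy(), sex=cohort.sex.copy())


@dataclass
class MrConfig:
    penalties: tuple[str, ...] = ("L1", "L2")
    m_imputations: int = 20
    folds: int = 5
    alpha_screen: float | None = None
    maf_min: float = 0.01
    mi_maxit: int = 25
    mi_learner: str = "tree"
    lambda_selection: str = "cross_validated"
    fixed_lambda: float = 0.0
    remove_outliers: bool = True
    pca_sd_threshold: float = 6.0
    mahalanobis_alpha: float = 1e-6
    exclude_ids: tuple = ()
    seed: int = 0


@dataclass
class MrResult:
    penalty: str
    per_imputation: dict              # dataset -> [(estimate, se), ...]
    pooled: dict                      # dataset -> (beta, se, df, p)
    meta: MetaEstimate
    instrument_corr: dict             # dataset -> mean corr(Z, X)
    outlier_candidates: dict          # dataset -> set of post hoc flagged ids
    pre_excluded: dict                # dataset -> list of pre-analysis outlier ids
    n_samples: dict                   # dataset -> n analyzed


def _preanalysis_outliers(quant: pd.DataFrame, sd_threshold: float,
                          mahal_alpha: float) -> np.ndarray:
    """Row indices flagged by iterated PCA trimming or extreme Mahalanobis
    distance on the complete-case standardized quantitative-trait matrix."""
    from .prs import pca_outlier_iterate

    M = quant.to_numpy(dtype=float)
    cc = np.all(np.isfinite(M), axis=1)
    idx = np.flatnonzero(cc)
    Mc = M[cc]
    if Mc.shape[0] < Mc.shape[1] + 2:
        return np.empty(0, dtype=int)
    flagged = set(pca_outlier_iterate(Mc, sd_threshold=sd_threshold))
    center = Mc.mean(axis=0)
    cov = np.cov(Mc, rowvar=False)
    cov += 1e-10 * np.eye(cov.shape[0])
    d = mahalanobis_distances(Mc, center, cov)
    cut = np.sqrt(sps.chi2.isf(mahal_alpha, df=Mc.shape[1]))
    flagged |= set(np.flatnonzero(d > cut))
    return idx[sorted(flagged)]


def _analyze_dataset(ds: MrDataset, cfg: MrConfig, penalties, seed_seq):
    """Impute once, run the instrument/causality chain per penalty."""
    ids = np.asarray(ds.sample_ids)
    keep = ~np.isin(ids, np.asarray(cfg.exclude_ids, dtype=ids.dtype)) \
        if len(cfg.exclude_ids) else np.ones(ids.size, dtype=bool)

    pheno = pd.concat([pd.Series(ds.Y, name="Y"), ds.W.reset_index(drop=True)],
                      axis=1)
    if ds.missing_mask is not None:
        pheno = pheno.mask(ds.missing_mask.reset_index(drop=True))

    pre_excluded = []
    if cfg.remove_outliers:
        quant = pd.concat([pd.Series(ds.X, name="X"), pheno], axis=1)
        out_idx = _preanalysis_outliers(quant, cfg.pca_sd_threshold,
                                        cfg.mahalanobis_alpha)
        pre_excluded = [ids[i] for i in out_idx if keep[i]]
        keep[out_idx] = False

    X = ds.X[keep]
    Y_mask = pheno.loc[keep].reset_index(drop=True)
    ids_kept = ids[keep]
    G = ds.G[keep]
    freq = G.mean(axis=0) / 2.0
    maf_ok = np.minimum(freq, 1.0 - freq) >= cfg.maf_min
    if not maf_ok.any():
        raise ValueError("no variants pass the MAF filter")
    G = G[:, maf_ok]

    mi_seed, run_seed = (int(s.generate_state(1)[0] % 2**31)
                         for s in seed_seq.spawn(2))
    # The imputation model must see the exposure and the variables driving
    # the missingness mechanism (age, sex) or the MAR assumption is not
    # ignorable; they are complete, so they act as predictors only.
    predictors = {"X": X}
    if ds.age is not None:
        predictors["age"] = np.asarray(ds.age, dtype=float)[keep]
    if ds.sex is not None:
        predictors["sex"] = np.asarray(ds.sex, dtype=float)[keep]
    mi_table = pd.concat([pd.DataFrame(predictors),
                          Y_mask.reset_index(drop=True)], axis=1)
    completed = mi_impute(mi_table, m=cfg.m_imputations, maxit=cfg.mi_maxit,
                          seed=mi_seed, learner=cfg.mi_learner)
    completed = [tab[Y_mask.columns] for tab in completed]
    # One fold assignment per dataset, shared by every imputation: the
    # instrument is rebuilt on each completed table, but re-randomizing
    # folds would leak fold-resampling noise into Rubin's
    # between-imputation variance and make the pooled test conservative.
    iseed = run_seed

    res = {pen: {"est": [], "corr": [], "flags": set()} for pen in penalties}
    for i, tab in enumerate(completed):
        Yi = tab["Y"].to_numpy(dtype=float)
        Wi = tab.drop(columns="Y")
        part = partition_covariates(Wi, X, Yi, cfg.alpha_screen)
        W_AB = Wi[[*part.set_A, *part.set_B]].to_numpy(dtype=float)
        for pen in penalties:
            spec = PenaltySpec(kind=pen, lam=cfg.fixed_lambda,
                               selection=cfg.lambda_selection)
            inst = build_instrument(X, G, W_AB, spec, K=cfg.folds, seed=iseed)
            adj_sets = classify_for_causality(Wi, inst.Z, Yi, cfg.alpha_screen)
            inst.adjusted_covariates = adj_sets.adjusted
            adjust = Wi[adj_sets.adjusted].to_numpy(dtype=float) \
                if adj_sets.adjusted else None
            fit = _causality_fit(Yi, inst.Z, adjust)
            res[pen]["est"].append((float(fit.coefficients[1]),
                                    float(fit.standard_errors[1])))
            res[pen]["corr"].append(float(np.corrcoef(inst.Z, X)[0, 1]))
            big = np.flatnonzero(fit.std_residuals > 1.0)
            if big.size:
                top = big[np.argsort(fit.leverage[big])[::-1][:10]]
                res[pen]["flags"].update(ids_kept[top].tolist())
    return res, pre_excluded, int(X.size)


def run_mr(datasets, config: MrConfig | None = None) -> dict:
    """Run the full MR chain; returns ``{penalty: MrResult}``.

    Imputations are generated once per dataset and shared across
    penalties, so L1/L2 differences reflect the penalty alone.
    """
    cfg = config or MrConfig()
    if cfg.m_imputations < 2:
        raise ValueError("need at least 2 imputations")
    if isinstance(datasets, MrDataset):
        datasets = [datasets]
    if not datasets:
        raise ValueError("need at least one dataset")
    penalties = tuple(cfg.penalties)
    root = np.random.SeedSequence(cfg.seed)
    ds_seeds = root.spawn(len(datasets))

    per_ds = {}
    for ds, ss in zip(datasets, ds_seeds):
        per_ds[ds.name] = _analyze_dataset(ds, cfg, penalties, ss)

    out = {}
    for pen in penalties:
        per_imp, pooled, corr, flags, pre_exc, ns = {}, {}, {}, {}, {}, {}
        for name, (res, pre, n) in per_ds.items():
            pairs = res[pen]["est"]
            per_imp[name] = pairs
            est = np.array([e for e, _ in pairs])
            var = np.array([s**2 for _, s in pairs])
            pooled[name] = rubin_combine(est, var)
            corr[name] = float(np.mean(res[pen]["corr"]))
            flags[name] = set(res[pen]["flags"])
            pre_exc[name] = list(pre)
            ns[name] = n
        meta = meta_fixed_ivw([pooled[k][0] for k in pooled],
                              [pooled[k][1] for k in pooled])
        out[pen] = MrResult(pen, per_imp, pooled, meta, corr, flags, pre_exc, ns)
    return out


def posthoc_outlier_rerun(results: dict | MrResult, datasets,
                          config: MrConfig | None = None):
    """Exclude every post hoc-flagged sample and rerun.

    A sample is flagged if, in at least one imputation run (any penalty),
    it was among the ten highest-leverage samples with standardized
    residual above one in the causality regression.  Returns
    ``(rerun_results, excluded_ids)``.
    """
    cfg = config or MrConfig()
    if isinstance(results, MrResult):
        results = {results.penalty: results}
    excluded: set = set()
    for r in results.values():
        for flagged in r.outlier_candidates.values():
            excluded |= set(flagged)
    if not excluded:
        return results, []
    if isinstance(datasets, MrDataset):
        datasets = [datasets]
    for ds in datasets:
        n_left = np.sum(~np.isin(np.asarray(ds.sample_ids), list(excluded)))
        if n_left <= ds.W.shape[1] + 2:
            raise ValueError(f"exclusion leaves dataset {ds.name!r} too small")
    cfg2 = replace(cfg, exclude_ids=tuple(sorted(excluded)))
    return run_mr(datasets, cfg2), sorted(excluded)
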