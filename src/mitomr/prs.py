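"""Polygenic-score projection and the cell-count / metabolic replication
workflow.

The averaged instrument weights from the MR stage are treated as a
polygenic risk score (PRS): imputed genotype-probability triplets are
collapsed to expected dosages DS = P(0/1) + 2 P(1/1), hard-called at 0.5
and 1.5, and dotted with the weights.  Trait associations use the design
trait ~ PRS + Age + Age^2 + Sex + Age:Sex + Age^2:Sex + PCs, optionally
adding neutrophil and platelet counts — the adjustment that probes
whether a metabolic signal is mediated by blood cell composition.
Outliers are removed by iterated PCA trimming of the cell-count matrix
and by null-model leverage/residual screens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import Family, RegressionFit, fit_linear, fit_logistic

__all__ = [
    "PrsWeights",
    "ReplicationResult",
    "expected_dosage",
    "hard_call",
    "compute_prs",
    "prepare_traits",
    "pca_outlier_iterate",
    "nullmodel_outliers",
    "metabolic_design",
    "prs_association",
]


@dataclass
class PrsWeights:
    variant_ids: list
    beta_G_bar: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.beta_G_bar = np.asarray(self.beta_G_bar, dtype=float).ravel()
        if len(self.variant_ids) != self.beta_G_bar.size:
            raise ValueError("ids and weights must align")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("variant ids must be unique")
        if not np.all(np.isfinite(self.beta_G_bar)):
            raise ValueError("weights must be finite")


@dataclass
class ReplicationResult:
    trait: str
    beta: float
    se: float
    p: float
    family: Family
    adjusted_for_cell_counts: bool
    n: int
    statistic: float = np.nan


def expected_dosage(gp_triplet) -> np.ndarray:
    """DS = P(0/1) + 2 P(1/1) from genotype-probability triplets.

    Accepts a single triplet or an array whose last axis has length 3.
    """
    gp = np.asarray(gp_triplet, dtype=float)
    if gp.shape[-1] != 3:
        raise ValueError("last axis must hold (P(0/0), P(0/1), P(1/1))")
    sums = gp.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("genotype probabilities must sum to 1")
    return gp[..., 1] + 2.0 * gp[..., 2]


def hard_call(ds) -> np.ndarray:
    """Hard genotype calls from expected dosage, thresholds 0.5 and 1.5.

    Boundary values are assigned upward: DS = 0.5 -> 1, DS = 1.5 -> 2.
    """
    d = np.asarray(ds, dtype=float)
    if np.any((d < 0) | (d > 2)):
        raise ValueError("dosages must lie in [0, 2]")
    return (d >= 0.5).astype(int) + (d >= 1.5).astype(int)


def compute_prs(weights: PrsWeights, calls, variant_ids=None) -> np.ndarray:
    """PRS = hard-call matrix @ averaged weights, aligned by variant id.

    ``calls`` is an n x m matrix; ``variant_ids`` names its columns
    (defaults to the weights' own order).  Any unmatched id is a hard
    error — silent dropping would misalign the score.
    """
    C = np.asarray(calls, dtype=float)
    if C.ndim != 2:
        raise ValueError("calls must be an n x m matrix")
    if variant_ids is None:
        variant_ids = list(weights.variant_ids)
    if C.shape[1] != len(variant_ids):
        raise ValueError("calls and variant_ids must align")
    pos = {v: i for i, v in enumerate(variant_ids)}
    missing = [v for v in weights.variant_ids if v not in pos]
    if missing:
        raise KeyError(f"variants absent from the call matrix: {missing[:5]}")
    order = [pos[v] for v in weights.variant_ids]
    return C[:, order] @ weights.beta_G_bar


# ---------------------------------------------------------------------------
# trait preparation


def prepare_traits(table: pd.DataFrame, sex, *,
                   cell_count_traits=("leukocyte", "neutrophil", "lymphocyte",
                                      "monocyte", "platelet"),
                   log_traits=(), drop_negative=()) -> pd.DataFrame:
    """Transform raw traits for association testing.

    When both ``leukocyte`` and ``lymphocyte_pct`` are present a
    ``lymphocyte`` count is derived as their product (the percentage is
    auto-rescaled to a fraction when values exceed 1).  Cell-count traits
    are log-transformed and standardized to mean 0 / SD 1 within each sex;
    ``log_traits`` are log-transformed only.  Negative-coded entries of
    ``drop_negative`` traits become NaN (dropped from that trait's
    analysis).
    """
    out = table.copy()
    sex = np.asarray(sex)
    if "leukocyte" in out and "lymphocyte_pct" in out:
        pct = out["lymphocyte_pct"].to_numpy(dtype=float)
        if np.nanmax(pct) > 1.0:
            pct = pct / 100.0
        out["lymphocyte"] = out["leukocyte"].to_numpy(dtype=float) * pct
        out = out.drop(columns="lymphocyte_pct")
    for col in drop_negative:
        if col in out:
            v = out[col].to_numpy(dtype=float)
            out[col] = np.where(v < 0, np.nan, v)
    for col in (*cell_count_traits, *log_traits):
        if col not in out:
            continue
        v = out[col].to_numpy(dtype=float)
        if np.any(v[np.isfinite(v)] <= 0):
            raise ValueError(f"nonpositive values submitted to log for {col!r}")
        out[col] = np.log(v)
    for col in cell_count_traits:
        if col not in out:
            continue
        for s in np.unique(sex):
            sel = sex == s
            v = out.loc[sel, col].to_numpy(dtype=float)
            mu, sd = np.nanmean(v), np.nanstd(v, ddof=1)
            out.loc[sel, col] = (v - mu) / sd
    return out


# ---------------------------------------------------------------------------
# outlier removal


def pca_outlier_iterate(matrix, sd_threshold: float = 6.0,
                        max_iter: int = 3) -> list:
    """Iterated PCA trimming of a trait matrix.

    Each iteration centers/scales the retained rows, computes principal
    component scores, and drops rows whose |score| exceeds
    ``sd_threshold`` standard deviations on any component; stops early
    when nothing is dropped.  Returns the dropped row indices (positions
    in the input).
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2 or M.shape[0] < 10:
        raise ValueError("need at least 10 samples and 2 traits")
    alive = np.arange(M.shape[0])
    excluded: list = []
    for _ in range(max_iter):
        sub = M[alive]
        mu, sd = sub.mean(axis=0), sub.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        Zs = (sub - mu) / sd
        U, S, _ = np.linalg.svd(Zs, full_matrices=False)
        scores = U * S
        score_sd = scores.std(axis=0, ddof=0)
        score_sd = np.where(score_sd > 0, score_sd, 1.0)
        bad = np.any(np.abs(scores) > sd_threshold * score_sd, axis=1)
        if not bad.any():
            break
        excluded.extend(alive[bad].tolist())
        alive = alive[~bad]
        if alive.size == 0:
            raise ValueError("all samples excluded by PCA trimming")
    return sorted(excluded)


def nullmodel_outliers(trait, design, family: Family = Family.linear, *,
                       r_hi: float = 6.0, r_mid: float = 2.0,
                       l_hi: float | None = None, max_iter: int = 2) -> list:
    """Leverage/residual outliers from a null covariate model.

    Excludes samples with |standardized residual| > ``r_hi``, or leverage
    above ``l_hi`` (default 3 p/n) together with |standardized residual| >
    ``r_mid``; refits up to ``max_iter`` times, stopping when an
    iteration excludes nothing.  Returns dropped row positions.
    """
    y = np.asarray(trait, dtype=float).ravel()
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    alive = np.arange(y.size)
    excluded: list = []
    for _ in range(max_iter):
        fitter = fit_linear if family == Family.linear else fit_logistic
        fit = fitter(y[alive], X[alive])
        cut_l = l_hi if l_hi is not None else 3.0 * fit.p / fit.n
        r = np.abs(fit.std_residuals)
        bad = (r > r_hi) | ((fit.leverage > cut_l) & (r > r_mid))
        if not bad.any():
            break
        excluded.extend(alive[bad].tolist())
        alive = alive[~bad]
    return sorted(excluded)


# ---------------------------------------------------------------------------
# association models


def metabolic_design(age, sex, pcs=None, extra: pd.DataFrame | None = None):
    """Design matrix Age + Age^2 + Sex + Age:Sex + Age^2:Sex + PCs (+extra),
    with intercept, as (matrix, column names)."""
    age = np.asarray(age, dtype=float).ravel()
    sex = np.asarray(sex, dtype=float).ravel()
    agec = age - age.mean()
    # list of pairs, not a dict: a duplicated covariate must surface as a
    # rank-deficiency error downstream, never be silently collapsed
    cols = [("intercept", np.ones(age.size)), ("age", agec),
            ("age2", agec**2), ("sex", sex), ("age_sex", agec * sex),
            ("age2_sex", agec**2 * sex)]
    if pcs is not None:
        P = np.asarray(pcs, dtype=float)
        if P.ndim == 1:
            P = P[:, None]
        for i in range(P.shape[1]):
            cols.append((f"pc{i + 1}", P[:, i]))
    if extra is not None:
        for c in extra.columns:
            cols.append((str(c), extra[c].to_numpy(dtype=float)))
    return np.column_stack([v for _, v in cols]), [k for k, _ in cols]


def prs_association(trait, prs, age, sex, pcs=None,
                    family: Family = Family.linear,
                    extra_adjust: pd.DataFrame | None = None,
                    trait_name: str = "trait") -> ReplicationResult:
    """Association of a trait with the PRS under the replication design.

    Rows with a missing trait value are dropped.  ``extra_adjust``
    typically carries neutrophil and platelet counts; the flag on the
    result records whether it was supplied.
    """
    y = np.asarray(trait, dtype=float).ravel()
    prs = np.asarray(prs, dtype=float).ravel()
    ok = np.isfinite(y)
    covs, names = metabolic_design(np.asarray(age)[ok], np.asarray(sex)[ok],
                                   None if pcs is None else np.asarray(pcs)[ok],
                                   None if extra_adjust is None
                                   else extra_adjust.reset_index(drop=True)
                                   .loc[ok].reset_index(drop=True))
    design = np.column_stack([covs[:, :1], prs[ok], covs[:, 1:]])
    fitter = fit_linear if family == Family.linear else fit_logistic
    fit: RegressionFit = fitter(y[ok], design)
    return ReplicationResult(
        trait=trait_name,
        beta=float(fit.coefficients[1]),
        se=float(fit.standard_errors[1]),
        p=float(fit.p_values[1]),
        family=family,
        adjusted_for_cell_counts=extra_adjust is not None,
        n=int(ok.sum()),
        statistic=float(fit.statistics[1]),
    )
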