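"""Core statistical engine shared by every pipeline stage.

Regression fits (OLS and logistic IRLS) with influence diagnostics,
penalized fits with an unpenalized covariate block, the rank-based inverse
normal transform, Rubin's rules for multiple-imputation pooling,
fixed-effect (inverse-variance weighted) and DerSimonian–Laird
random-effects meta-analysis, Benjamini–Hochberg q-values with Storey's
null-proportion correction, Bonferroni thresholds, and Mahalanobis
distances.

Everything is deterministic and dependency-light: fits are built on
numpy/scipy linear algebra so that leverage (hat-matrix diagonal) and
standardized residuals — needed by the outlier procedures downstream — come
out of the same decomposition as the coefficients.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats as sps

__all__ = [
    "Family",
    "RegressionFit",
    "PenaltyKind",
    "PenaltySpec",
    "MetaEstimate",
    "QTable",
    "ConvergenceError",
    "inverse_rank_normal",
    "fit_linear",
    "fit_logistic",
    "fit_penalized",
    "rubin_combine",
    "meta_fixed_ivw",
    "meta_random_dl",
    "qvalues_bh_storey",
    "bonferroni_threshold",
    "mahalanobis_distances",
]


class ConvergenceError(RuntimeError):
    """Raised when an iterative fit fails to converge (e.g. separation)."""


class Family(str, enum.Enum):
    linear = "linear"
    logistic = "logistic"


@dataclass
class RegressionFit:
    """A fitted regression with the diagnostics the pipeline needs.

    ``leverage`` is the hat-matrix diagonal; ``std_residuals`` are
    internally studentized (linear) or Pearson residuals scaled by
    ``sqrt(1 - h)`` (logistic).
    """

    coefficients: np.ndarray
    standard_errors: np.ndarray
    statistics: np.ndarray
    p_values: np.ndarray
    residuals: np.ndarray
    std_residuals: np.ndarray
    leverage: np.ndarray
    family: Family
    n: int
    p: int


class PenaltyKind(str, enum.Enum):
    L1 = "L1"
    L2 = "L2"


@dataclass
class PenaltySpec:
    kind: PenaltyKind = PenaltyKind.L2
    lam: float = 0.0
    selection: str = "fixed"  # "fixed" | "cross_validated"

    def __post_init__(self) -> None:
        self.kind = PenaltyKind(self.kind)
        if self.lam < 0:
            raise ValueError("penalty lambda must be nonnegative")
        if self.selection not in ("fixed", "cross_validated"):
            raise ValueError(f"unknown selection rule {self.selection!r}")


@dataclass
class MetaEstimate:
    beta: float
    se: float
    z: float
    p: float
    method: str  # "fixed_ivw" | "random_dl"
    tau2: float
    Q: float
    k: int


@dataclass
class QTable:
    p_values: np.ndarray
    q_values: np.ndarray
    pi0: float


# ---------------------------------------------------------------------------
# transforms


def inverse_rank_normal(values) -> np.ndarray:
    """Rank-based inverse normal transform, Phi^-1((r - 0.5) / n).

    Ties receive average ranks, so the transform is deterministic and
    order-independent.  Tie-free input maps to an exactly symmetric set of
    normal quantiles (sample mean 0).  All-identical input is degenerate —
    every value lands on the median quantile 0 — and is signaled with a
    warning.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-d vector")
    if x.size < 2 or not np.all(np.isfinite(x)):
        raise ValueError("need at least 2 finite values")
    if np.all(x == x[0]):
        warnings.warn("degenerate input: all values identical")
    ranks = sps.rankdata(x, method="average")
    return sps.norm.ppf((ranks - 0.5) / x.size)


# ---------------------------------------------------------------------------
# regression


def _design_matrix(design) -> np.ndarray:
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def fit_linear(y, design) -> RegressionFit:
    """Ordinary least squares with t-based p-values and hat diagnostics."""
    y = np.asarray(y, dtype=float).ravel()
    X = _design_matrix(design)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    Q, R = np.linalg.qr(X)
    rdiag = np.abs(np.diag(R))
    if np.any(rdiag < max(n, p) * np.finfo(float).eps * rdiag.max(initial=1.0)):
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    beta = linalg.solve_triangular(R, Q.T @ y)
    fitted = X @ beta
    resid = y - fitted
    df = n - p
    rss = float(resid @ resid)
    sigma2 = rss / df
    Rinv = linalg.solve_triangular(R, np.eye(p))
    XtX_inv = Rinv @ Rinv.T
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pvals = 2 * sps.t.sf(np.abs(tstat), df)
    leverage = np.einsum("ij,ij->i", Q, Q)
    denom = np.sqrt(np.maximum(sigma2 * (1.0 - leverage), np.finfo(float).tiny))
    std_resid = resid / denom
    return RegressionFit(beta, se, tstat, pvals, resid, std_resid,
                         np.clip(leverage, 0.0, 1.0), Family.linear, n, p)


def fit_logistic(y, design, *, max_iter: int = 100, tol: float = 1e-10) -> RegressionFit:
    """Maximum-likelihood logistic regression via IRLS with Wald z tests.

    Complete separation is declared (``ConvergenceError``) when any
    coefficient exceeds 15 on the standardized design, or when IRLS fails
    to converge.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = _design_matrix(design)
    n, p = X.shape
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("outcome must be coded 0/1")
    if classes.size < 2:
        raise ValueError("single-class outcome")
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")

    col_sd = X.std(axis=0)
    scale = np.where(col_sd > 0, col_sd, 1.0)  # constant columns kept as-is

    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        z = eta + (y - mu) / w
        sw = np.sqrt(w)
        Q, R = np.linalg.qr(X * sw[:, None])
        new_beta = linalg.solve_triangular(R, Q.T @ (z * sw))
        step = np.max(np.abs(new_beta - beta))
        beta = new_beta
        if np.max(np.abs(beta * scale)) > 15.0:
            raise ConvergenceError("separation suspected: standardized |coefficient| > 15")
        if step < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError("IRLS did not converge")

    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    sw = np.sqrt(w)
    Q, R = np.linalg.qr(X * sw[:, None])
    Rinv = linalg.solve_triangular(R, np.eye(p))
    cov = Rinv @ Rinv.T
    se = np.sqrt(np.diag(cov))
    zstat = beta / se
    pvals = 2 * sps.norm.sf(np.abs(zstat))
    leverage = np.clip(np.einsum("ij,ij->i", Q, Q), 0.0, 1.0)
    resid = y - mu
    pearson = resid / sw
    std_resid = pearson / np.sqrt(np.maximum(1.0 - leverage, np.finfo(float).tiny))
    return RegressionFit(beta, se, zstat, pvals, resid, std_resid,
                         leverage, Family.logistic, n, p)


# ---------------------------------------------------------------------------
# penalized regression (in _penalized.py, re-exported here)

from ._penalized import fit_penalized  # noqa: E402


# ---------------------------------------------------------------------------
# pooling and meta-analysis


def rubin_combine(estimates, variances, *, df_method: str = "m_minus_2"):
    """Pool multiple-imputation estimates with Rubin's rules.

    Total variance T = W̄ + (1 + 1/m)·B, with W̄ the mean within-imputation
    variance and B the between-imputation variance.  ``df_method="m_minus_2"``
    uses df = m − 2 (so m = 1000 imputations are referred to a t with 998
    degrees of freedom — the pipeline convention); ``df_method="barnard_rubin"``
    uses the (m − 1)·(1 + W̄ / ((1 + 1/m)·B))² adjustment.

    Returns ``(beta, se, df, p)``.
    """
    est = np.asarray(estimates, dtype=float).ravel()
    var = np.asarray(variances, dtype=float).ravel()
    m = est.size
    if m < 2:
        raise ValueError("need at least 2 imputations")
    if var.size != m:
        raise ValueError("estimates and variances must have equal length")
    if np.any(var <= 0):
        raise ValueError("variances must be positive")
    beta = float(est.mean())
    wbar = float(var.mean())
    B = float(est.var(ddof=1))
    T = wbar + (1.0 + 1.0 / m) * B
    se = float(np.sqrt(T))
    if df_method == "m_minus_2":
        df = float(m - 2)
    elif df_method == "barnard_rubin":
        if B == 0:
            df = float(np.inf)
        else:
            r = (1.0 + 1.0 / m) * B / wbar
            df = float((m - 1) * (1.0 + 1.0 / r) ** 2)
    else:
        raise ValueError(f"unknown df_method {df_method!r}")
    p = float(2 * sps.t.sf(abs(beta) / se, df)) if np.isfinite(df) else \
        float(2 * sps.norm.sf(abs(beta) / se))
    return beta, se, df, p


def meta_fixed_ivw(betas, ses) -> MetaEstimate:
    """Fixed-effect inverse-variance weighted meta-analysis with a Z test."""
    b = np.asarray(betas, dtype=float).ravel()
    s = np.asarray(ses, dtype=float).ravel()
    if b.size == 0:
        raise ValueError("no studies to combine")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    z = beta / se
    Q = float(np.sum(w * (b - beta) ** 2))
    return MetaEstimate(beta, se, z, float(2 * sps.norm.sf(abs(z))),
                        "fixed_ivw", 0.0, Q, int(b.size))


def meta_random_dl(betas, ses) -> MetaEstimate:
    """DerSimonian–Laird random-effects meta-analysis."""
    b = np.asarray(betas, dtype=float).ravel()
    s = np.asarray(ses, dtype=float).ravel()
    k = b.size
    if k < 2:
        raise ValueError("need at least 2 studies for random effects")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / s**2
    beta_fe = np.sum(w * b) / np.sum(w)
    Q = float(np.sum(w * (b - beta_fe) ** 2))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    wr = 1.0 / (s**2 + tau2)
    beta = float(np.sum(wr * b) / np.sum(wr))
    se = float(np.sqrt(1.0 / np.sum(wr)))
    z = beta / se
    return MetaEstimate(beta, se, z, float(2 * sps.norm.sf(abs(z))),
                        "random_dl", float(tau2), Q, int(k))


# ---------------------------------------------------------------------------
# multiplicity


def _storey_pi0(p: np.ndarray) -> float:
    # pi0(lambda) = #{p > lambda} / (n (1 - lambda)) over a lambda grid,
    # smoothed with a cubic polynomial and read off at the largest lambda.
    lams = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([np.mean(p > l) / (1.0 - l) for l in lams])
    coefs = np.polyfit(lams, pi0_lam, deg=3)
    pi0 = float(np.polyval(coefs, lams[-1]))
    return float(np.clip(pi0, np.finfo(float).tiny, 1.0))


def qvalues_bh_storey(p_values, *, pi0: float | None = None) -> QTable:
    """Benjamini–Hochberg q-values scaled by Storey's estimated pi0.

    ``q_i = pi0 * min over {j : p_j >= p_i} of n*p_j / rank_j``, clipped to
    [0, 1].  Forcing ``pi0=1`` reduces exactly to classical BH.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if pi0 is None:
        pi0 = _storey_pi0(p)
    if not (0 < pi0 <= 1):
        raise ValueError("pi0 must lie in (0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(pi0 * q_sorted, 0.0, 1.0)
    return QTable(p, q, float(pi0))


def bonferroni_threshold(n_tests: int, alpha: float) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# outlier geometry


def mahalanobis_distances(rows, center, covariance) -> np.ndarray:
    """d_i = sqrt((x_i - mu)' Sigma^-1 (x_i - mu)) for each row."""
    X = np.atleast_2d(np.asarray(rows, dtype=float))
    mu = np.asarray(center, dtype=float).ravel()
    S = np.asarray(covariance, dtype=float)
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("covariance is not positive definite") from exc
    diff = X - mu
    sol = linalg.solve_triangular(L, diff.T, lower=True)
    return np.sqrt(np.einsum("ij,ij->j", sol, sol))
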