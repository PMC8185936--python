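"""Penalized least squares with an unpenalized covariate block.

Solves

    min_{beta, gamma}  1/2 ||y - P beta - F gamma||^2 + lam * pen(beta)

with pen = ||beta||_1 (L1) or 1/2 ||beta||_2^2 (L2); the free block F is
never penalized.  The free block is handled exactly by Frisch–Waugh
partialling: y and (scaled) P are residualized on F, the penalized problem
is solved on the residualized data, and gamma is recovered by OLS of the
partial residual on F — equivalent to the joint minimization for both
penalties because gamma enters the objective quadratically without
penalty.

The L1 solver is cyclic coordinate descent on the Gram matrix
(covariance updates), converging when the largest coefficient change in a
sweep falls below 1e-7; L2 is a closed-form solve.  Penalized columns are
standardized to unit variance internally by default and coefficients are
returned on the original scale, making lam comparable across variants.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

_CD_TOL = 1e-7
_CD_MAX_SWEEPS = 100_000


def _as_2d(a, n: int) -> np.ndarray:
    if a is None:
        return np.empty((n, 0))
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return a


def _residualize(y: np.ndarray, P: np.ndarray, F: np.ndarray):
    """Project y and the columns of P off the column space of F."""
    if F.shape[1] == 0:
        return y, P, None, None
    Q, R = np.linalg.qr(F)
    rdiag = np.abs(np.diag(R))
    if np.any(rdiag < F.shape[0] * np.finfo(float).eps * rdiag.max(initial=1.0)):
        raise np.linalg.LinAlgError("free block is rank deficient")
    y_t = y - Q @ (Q.T @ y)
    P_t = P - Q @ (Q.T @ P)
    return y_t, P_t, Q, R


def _soft(x: float, t: float) -> float:
    return np.sign(x) * max(abs(x) - t, 0.0)


def solve_l1_gram(G: np.ndarray, c: np.ndarray, lam: float,
                  beta0: np.ndarray | None = None) -> np.ndarray:
    """Lasso via cyclic coordinate descent on G = P'P, c = P'y."""
    m = c.size
    beta = np.zeros(m) if beta0 is None else beta0.copy()
    r = c - G @ beta  # residual correlations
    for _ in range(_CD_MAX_SWEEPS):
        max_delta = 0.0
        for j in range(m):
            gjj = G[j, j]
            if gjj <= 0:
                continue
            rho = r[j] + gjj * beta[j]
            new = _soft(rho, lam) / gjj
            d = new - beta[j]
            if d != 0.0:
                beta[j] = new
                r -= G[:, j] * d
                if abs(d) > max_delta:
                    max_delta = abs(d)
        if max_delta < _CD_TOL:
            break
    return beta


def solve_l2_gram(G: np.ndarray, c: np.ndarray, lam: float) -> np.ndarray:
    m = c.size
    if lam == 0.0:
        return np.linalg.solve(G, c)
    return np.linalg.solve(G + lam * np.eye(m), c)


def fit_penalized(y, penalized_block, free_block, penalty, *,
                  standardize: bool = True):
    """Fit the penalized regression; returns ``(beta, gamma)``.

    ``beta`` are the penalized coefficients on the original column scale,
    ``gamma`` the unpenalized free-block coefficients.  ``penalty`` is a
    :class:`~mitomr.stats.PenaltySpec`; its ``selection`` field is ignored
    here (cross-validated selection happens in the instrument builder).
    """
    from .stats import PenaltyKind  # local import to avoid a cycle

    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    P = _as_2d(penalized_block, n)
    F = _as_2d(free_block, n)
    if penalty.lam < 0:
        raise ValueError("negative lambda")

    if standardize:
        sd = P.std(axis=0, ddof=0)
        scale = np.where(sd > 0, sd, 1.0)
    else:
        scale = np.ones(P.shape[1])
    Ps = P / scale

    y_t, P_t, Q, R = _residualize(y, Ps, F)
    G = P_t.T @ P_t
    c = P_t.T @ y_t

    if penalty.kind is PenaltyKind.L1:
        beta_std = solve_l1_gram(G, c, penalty.lam)
    else:
        beta_std = solve_l2_gram(G, c, penalty.lam)
    beta = beta_std / scale

    if F.shape[1]:
        gamma = linalg.solve_triangular(R, Q.T @ (y - P @ beta))
    else:
        gamma = np.empty(0)
    return beta, gamma


# ---------------------------------------------------------------------------
# cross-validated lambda selection


def lambda_grid(kind, lam_max: float, n: int, size: int = 25) -> np.ndarray:
    """Decreasing lambda grid: lasso from lam_max down 3 decades; ridge a
    fixed span of shrinkage factors scaled by n."""
    from .stats import PenaltyKind

    if PenaltyKind(kind) is PenaltyKind.L1:
        return lam_max * np.logspace(0, -3, size)
    return n * np.logspace(3, -3, size)


def select_lambda_cv(y, penalized_block, free_block, kind, *,
                     n_folds: int = 5, rng: np.random.Generator,
                     standardize: bool = True, one_se: bool = True,
                     grid_size: int = 25) -> float:
    """Pick lambda by K-fold cross-validated prediction error.

    With ``one_se`` the largest lambda whose mean CV error is within one
    standard error of the minimum is chosen (more shrinkage, fewer false
    instrument weights); otherwise the minimizer.
    """
    from .stats import PenaltyKind, PenaltySpec

    kind = PenaltyKind(kind)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    P = _as_2d(penalized_block, n)
    F = _as_2d(free_block, n)
    if n_folds < 2 or n_folds > n:
        raise ValueError("invalid fold count")

    if standardize:
        sd = P.std(axis=0, ddof=0)
        scale = np.where(sd > 0, sd, 1.0)
    else:
        scale = np.ones(P.shape[1])

    # lam_max from the full standardized data so the grid is fold-invariant
    y_t, P_t, _, _ = _residualize(y, P / scale, F)
    lam_max = float(np.max(np.abs(P_t.T @ y_t))) if P.shape[1] else 0.0
    if lam_max == 0.0:
        lam_max = 1.0
    grid = lambda_grid(kind, lam_max, n, grid_size)

    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[perm] = np.arange(n) % n_folds

    errs = np.empty((n_folds, grid.size))
    for k in range(n_folds):
        tr = fold_of != k
        va = ~tr
        ytr, Ptr, Ftr = y[tr], P[tr], F[tr]
        Ps = Ptr / scale
        yt, Pt, Q, R = _residualize(ytr, Ps, Ftr)
        G = Pt.T @ Pt
        c = Pt.T @ yt
        if kind is PenaltyKind.L2:
            d, V = np.linalg.eigh(G)
            d = np.maximum(d, 0.0)
            Vc = V.T @ c
            betas = (V @ (Vc[:, None] / (d[:, None] + grid[None, :]))).T
        else:
            betas = np.empty((grid.size, c.size))
            warm = None
            for gi, lam in enumerate(grid):
                warm = solve_l1_gram(G, c, lam, warm)
                betas[gi] = warm
        for gi in range(grid.size):
            b = betas[gi] / scale
            if Ftr.shape[1]:
                gamma = linalg.solve_triangular(R, Q.T @ (ytr - Ptr @ b))
                pred = P[va] @ b + F[va] @ gamma
            else:
                pred = P[va] @ b
            errs[k, gi] = np.mean((y[va] - pred) ** 2)

    mean_err = errs.mean(axis=0)
    se_err = errs.std(axis=0, ddof=1) / np.sqrt(n_folds)
    best = int(np.argmin(mean_err))
    if not one_se:
        return float(grid[best])
    cutoff = mean_err[best] + se_err[best]
    # grid is decreasing, so the first index meeting the cutoff is the
    # largest admissible lambda
    idx = int(np.argmax(mean_err <= cutoff))
    return float(grid[idx])
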