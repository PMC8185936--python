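"""Multiple imputation by chained equations.

Per-variable learner is a regression tree whose imputations are drawn
from the observed donor values in the predicted terminal node (so imputed
values are always observed values of that variable), with a Bayesian
linear-regression fallback for small samples or when requested.  Each of
the m imputations runs an independent, deterministically seeded chain of
``maxit`` sweeps over the incomplete variables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

__all__ = ["mi_impute"]

_TREE_KW = dict(max_depth=5, min_samples_leaf=10)
_MIN_N_FOR_TREE = 50


def _bayes_linear_draw(Xobs, yobs, Xmis, rng):
    n, p = Xobs.shape
    XtX = Xobs.T @ Xobs + 1e-8 * np.eye(p)
    XtX_inv = np.linalg.inv(XtX)
    beta_hat = XtX_inv @ (Xobs.T @ yobs)
    resid = yobs - Xobs @ beta_hat
    df = max(n - p, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(df)
    L = np.linalg.cholesky(sigma2 * XtX_inv + 1e-12 * np.eye(p))
    beta = beta_hat + L @ rng.standard_normal(p)
    return Xmis @ beta + rng.normal(0.0, np.sqrt(sigma2), size=Xmis.shape[0])


def _tree_draw(Xobs, yobs, Xmis, rng):
    tree = DecisionTreeRegressor(random_state=int(rng.integers(2**31)), **_TREE_KW)
    tree.fit(Xobs, yobs)
    leaves_obs = tree.apply(Xobs)
    leaves_mis = tree.apply(Xmis)
    donors: dict[int, np.ndarray] = {}
    for leaf in np.unique(leaves_mis):
        donors[leaf] = yobs[leaves_obs == leaf]
    out = np.empty(Xmis.shape[0])
    for i, leaf in enumerate(leaves_mis):
        pool = donors[leaf]
        out[i] = pool[rng.integers(pool.size)] if pool.size else yobs[rng.integers(yobs.size)]
    return out


def _one_imputation(values: np.ndarray, miss: np.ndarray, order, rng,
                    maxit: int, learner: str) -> np.ndarray:
    filled = values.copy()
    for j in np.flatnonzero(miss.any(axis=0)):
        obs = values[~miss[:, j], j]
        filled[miss[:, j], j] = rng.choice(obs, size=int(miss[:, j].sum()))
    for _ in range(maxit):
        for j in order:
            mis_j = miss[:, j]
            others = np.delete(np.arange(values.shape[1]), j)
            X = filled[:, others]
            Xobs, yobs, Xmis = X[~mis_j], values[~mis_j, j], X[mis_j]
            use_tree = learner == "tree" and yobs.size >= _MIN_N_FOR_TREE
            draw = _tree_draw if use_tree else _bayes_linear_draw
            filled[mis_j, j] = draw(Xobs, yobs, Xmis, rng)
    return filled


def mi_impute(data: pd.DataFrame, m: int, maxit: int = 25, seed=0,
              learner: str = "tree") -> list[pd.DataFrame]:
    """Impute missing (NaN) entries; returns ``m`` completed copies.

    ``learner`` is ``"tree"`` (donor draws from regression-tree terminal
    nodes) or ``"gaussian"`` (Bayesian linear regression with posterior
    and noise draws).  The tree learner falls back to the Gaussian one
    when fewer than 50 complete observations are available for a variable.
    """
    if learner not in ("tree", "gaussian"):
        raise ValueError(f"unknown learner {learner!r}")
    if m < 1:
        raise ValueError("need at least one imputation")
    if not all(np.issubdtype(dt, np.number) for dt in data.dtypes):
        raise ValueError("all columns must be numeric")
    values = data.to_numpy(dtype=float)
    miss = np.isnan(values)
    if miss.all(axis=0).any():
        bad = data.columns[miss.all(axis=0)].tolist()
        raise ValueError(f"variables entirely missing: {bad}")
    if not miss.any():
        return [data.copy() for _ in range(m)]
    # visit incomplete variables from least to most missing
    counts = miss.sum(axis=0)
    order = [j for j in np.argsort(counts, kind="stable") if counts[j] > 0]
    streams = np.random.SeedSequence(seed).spawn(m)
    out = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        filled = _one_imputation(values, miss, order, rng, maxit, learner)
        out.append(pd.DataFrame(filled, columns=data.columns, index=data.index))
    return out
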