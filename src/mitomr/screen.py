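"""Phenome-wide screen of a score against a curated phenotype table.

Phenotype curation follows a PHESANT-style scheme: every continuous
variable is emitted twice (raw and inverse-rank-normalized), binary
variables are kept as-is, unordered categorical variables become
one-vs-rest indicators tested by logistic regression, and sex-specific
categorical traits are excluded.  False-discovery control applies a
Benjamini–Hochberg procedure with Storey's null-proportion correction to
two families: the primary family pools categorical/binary tests with the
normalized continuous versions, the secondary with the raw versions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import (ConvergenceError, Family, fit_linear, fit_logistic,
                    inverse_rank_normal, qvalues_bh_storey)
from .prs import metabolic_design

__all__ = ["CuratedVariable", "ScreenRow", "curate", "run_screen"]


@dataclass
class CuratedVariable:
    name: str
    kind: str          # continuous_raw | continuous_irn | binary | categorical_unordered
    values: np.ndarray
    provenance: str = ""
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass
class ScreenRow:
    name: str
    kind: str
    beta: float
    se: float
    p: float
    q: float
    n: int


def _is_sex_specific(values: np.ndarray, sex: np.ndarray | None,
                     min_share: float = 0.02) -> bool:
    """Nearly all carriers of the trait belong to one sex."""
    if sex is None:
        return False
    ok = np.isfinite(values)
    obs = values[ok]
    if np.isin(obs, (0.0, 1.0)).all():    # binary: look at the carriers
        sexes = np.asarray(sex)[ok][obs == 1.0]
    else:                                  # categorical: at observed rows
        sexes = np.asarray(sex)[ok]
    if sexes.size == 0:
        return False
    vals, counts = np.unique(sexes, return_counts=True)
    return counts.max() / sexes.size > 1.0 - min_share


def curate(table: pd.DataFrame, metadata: pd.DataFrame,
           sex=None) -> list[CuratedVariable]:
    """Curate phenotype columns into testable variables.

    ``metadata`` needs columns (column, type, sex_specific) with type one
    of continuous / binary / categorical; undeclared columns are an
    error.  Continuous variables yield a raw/IRN pair; categorical
    variables yield one-vs-rest binary indicators per level; sex-specific
    categorical traits and constant columns are excluded with a reason.
    """
    meta = metadata.set_index("column")
    missing = [c for c in table.columns if c not in meta.index]
    if missing:
        raise ValueError(f"columns without declared type: {missing}")
    sex = None if sex is None else np.asarray(sex)
    out: list[CuratedVariable] = []
    for col in table.columns:
        kind = str(meta.loc[col, "type"])
        sex_specific = bool(meta.loc[col, "sex_specific"]) if \
            "sex_specific" in meta.columns else False
        v = table[col].to_numpy(dtype=float)
        obs = v[np.isfinite(v)]
        if obs.size == 0 or np.all(obs == obs[0]):
            out.append(CuratedVariable(col, kind, v, excluded=True,
                                       exclusion_reason="constant"))
            continue
        if kind == "continuous":
            out.append(CuratedVariable(col, "continuous_raw", v))
            irn = np.full_like(v, np.nan)
            ok = np.isfinite(v)
            irn[ok] = inverse_rank_normal(v[ok])
            out.append(CuratedVariable(col, "continuous_irn", irn,
                                       provenance="inverse rank normal of raw"))
        elif kind == "binary":
            if sex_specific or _is_sex_specific(v, sex):
                out.append(CuratedVariable(col, "binary", v, excluded=True,
                                           exclusion_reason="sex-specific"))
            else:
                out.append(CuratedVariable(col, "binary", v))
        elif kind == "categorical":
            if sex_specific or _is_sex_specific(v, sex):
                out.append(CuratedVariable(col, "categorical_unordered", v,
                                           excluded=True,
                                           exclusion_reason="sex-specific"))
                continue
            levels = np.unique(obs)
            for lev in levels:
                ind = np.where(np.isfinite(v), (v == lev).astype(float), np.nan)
                out.append(CuratedVariable(
                    f"{col}=={lev:g}", "categorical_unordered", ind,
                    provenance=f"one-vs-rest indicator of {col}"))
        else:
            raise ValueError(f"undeclared/unknown type {kind!r} for {col!r}")
    return out


def _fit_one(var: CuratedVariable, score, age, sex, pcs, extra):
    y = var.values
    ok = np.isfinite(y)
    covs, _ = metabolic_design(np.asarray(age)[ok], np.asarray(sex)[ok],
                               None if pcs is None else np.asarray(pcs)[ok],
                               None if extra is None else
                               extra.loc[ok].reset_index(drop=True))
    design = np.column_stack([covs[:, :1], np.asarray(score)[ok], covs[:, 1:]])
    logistic = var.kind in ("binary", "categorical_unordered")
    fitter = fit_logistic if logistic else fit_linear
    try:
        fit = fitter(y[ok], design)
    except (ConvergenceError, ValueError, np.linalg.LinAlgError):
        return None
    return ScreenRow(var.name, var.kind, float(fit.coefficients[1]),
                     float(fit.standard_errors[1]), float(fit.p_values[1]),
                     np.nan, int(ok.sum()))


def run_screen(score, curated: list[CuratedVariable], age, sex, pcs=None,
               adjust_cell_counts: bool = False,
               cell_counts: pd.DataFrame | None = None) -> dict:
    """Screen every curated variable against the score.

    Returns ``{"primary": [ScreenRow...], "secondary": [...]}`` where the
    primary q-value family pools categorical/binary tests with the
    IRN continuous versions and the secondary uses the raw versions.
    With ``adjust_cell_counts`` the neutrophil/platelet columns of
    ``cell_counts`` join the covariates.
    """
    extra = None
    if adjust_cell_counts:
        if cell_counts is None:
            raise ValueError("adjust_cell_counts requires a cell_counts table")
        extra = cell_counts[["neutrophil", "platelet"]].reset_index(drop=True)
    rows: dict[str, ScreenRow] = {}
    kinds: dict[str, str] = {}
    for var in curated:
        if var.excluded:
            continue
        row = _fit_one(var, score, age, sex, pcs, extra)
        if row is not None:
            rows[f"{var.name}|{var.kind}"] = row
            kinds[f"{var.name}|{var.kind}"] = var.kind
    out = {}
    for fam, cont_kind in (("primary", "continuous_irn"),
                           ("secondary", "continuous_raw")):
        keys = [k for k, kd in kinds.items()
                if kd in ("binary", "categorical_unordered", cont_kind)]
        if not keys:
            raise ValueError(f"{fam} family has zero tests")
        ps = np.array([rows[k].p for k in keys])
        qt = qvalues_bh_storey(ps)
        fam_rows = []
        for k, q in zip(keys, qt.q_values):
            r = rows[k]
            fam_rows.append(ScreenRow(r.name, r.kind, r.beta, r.se, r.p,
                                      float(q), r.n))
        fam_rows.sort(key=lambda r: r.p)
        out[fam] = fam_rows
    return out
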