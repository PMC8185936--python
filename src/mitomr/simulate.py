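"""Synthetic cohort generator.

Emulates the statistical structure the downstream analyses assume: a
genotype matrix with a polygenic effect on log mitochondrial copy number
(the exposure X), a latent confounder U linking X to log fasting insulin
(the outcome Y), covariate blocks that are outcome-associated,
exposure-associated, or null, three acquisition batches with mean shifts
on the raw copy-number scale, age/sex effects, missing-at-random phenotype
gaps, a blood-composition latent factor shared between the exposure's
polygenic signal and neutrophil/platelet counts, and Poisson sequencing
depth on the mitochondrial contig (uniform for WGS, probe-peaked for WES).

All generation is reproducible from ``(config, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "DepthParams",
    "CohortConfig",
    "SyntheticCohort",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_coverage",
    "coverage_for_cohort",
]

MT_GENOME_LENGTH = 16569

# fixed structural loadings (standardized scale); variance they contribute
# to X is loading^2 because every source is unit variance
_AGE_LOADING = 0.12
_AGE2_LOADING = 0.07
_SEX_LOADING = 0.10
_WB_LOADING = 0.10        # per exposure-linked covariate, on X
_WA_LOADING = 0.30        # per outcome-linked covariate, on Y
_EPS_Y_SD = 0.40
_NEUT_LOADING = 0.80      # neutrophil latent on composition factor
_PLT_LOADING = 0.70       # platelet latent on composition factor


@dataclass
class DepthParams:
    """Sequencing-depth model for the mitochondrial contig."""

    haploid_autosomal_coverage: float = 20.0
    mtcn_location: float = math.log(200.0)   # mean of ln(copy number)
    mtcn_scale: float = 0.25                 # sd of ln(copy number)
    mt_genome_length: int = MT_GENOME_LENGTH
    wes_profile_peakedness: float = 0.9      # 0 = uniform (WGS-like)
    hapcov_jitter_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.haploid_autosomal_coverage <= 0 or self.mt_genome_length <= 0:
            raise ValueError("depth parameters must be positive")
        if not (0 <= self.wes_profile_peakedness <= 1):
            raise ValueError("peakedness must lie in [0, 1]")


@dataclass
class CohortConfig:
    n_samples: int = 2000
    n_variants: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    theta: float = 0.15                      # causal effect of X on Y
    h2_instrument: float = 0.2               # var fraction of X from G
    confounder_strengths: tuple[float, float] = (0.3, 0.3)   # (delta_X, delta_Y)
    n_covariates: dict = field(default_factory=lambda: {
        "outcome_linked": 3, "exposure_linked": 3, "null": 4})
    batch_offsets: tuple[float, ...] = (0.0, 15.0, -10.0)
    missing_rate: float = 0.05
    composition_loading: float = 0.5         # genetic share of the cell-mix factor
    gp_jitter: float = 0.05
    depth_params: DepthParams = field(default_factory=DepthParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.depth_params, dict):
            self.depth_params = DepthParams(**self.depth_params)
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if not (0 <= self.h2_instrument < 1):
            raise ValueError("h2_instrument must lie in [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if not (0 <= self.composition_loading <= 1):
            raise ValueError("composition_loading must lie in [0, 1]")
        explained = (self.h2_instrument
                     + self.confounder_strengths[0] ** 2
                     + self.n_covariates.get("exposure_linked", 0) * _WB_LOADING ** 2
                     + _AGE_LOADING ** 2 + _AGE2_LOADING ** 2 + _SEX_LOADING ** 2)
        if explained > 0.98:
            raise ValueError(
                f"variance components of X sum to {explained:.3f} > 0.98")
        self._explained_x = explained


@dataclass
class SyntheticCohort:
    """A simulated cohort; ``truth`` records every generative parameter."""

    config: CohortConfig
    sample_ids: list
    variant_ids: list
    dosages: np.ndarray          # n x m, from GP
    gp_triplets: np.ndarray      # n x m x 3
    mafs: np.ndarray
    W: pd.DataFrame              # covariate table, group-labeled columns
    U: np.ndarray
    X: np.ndarray                # ln(MT-CN), truth level
    Y: np.ndarray                # ln(insulin)
    age: np.ndarray
    sex: np.ndarray              # 0 = male, 1 = female
    batch: np.ndarray            # labels
    raw_mtcn: np.ndarray         # exp(X) + batch offset (observed scale)
    cell_counts: pd.DataFrame
    missing_mask: pd.DataFrame   # bool, over Y and W columns
    truth: dict

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def phenotype_table(self, *, masked: bool = True) -> pd.DataFrame:
        """Y plus covariates, with NaN where the missingness mask applies."""
        tab = pd.concat([pd.Series(self.Y, name="Y"), self.W.reset_index(drop=True)],
                        axis=1)
        if masked:
            tab = tab.mask(self.missing_mask.reset_index(drop=True))
        return tab


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_genotypes(n: int, m: int, maf_range=(0.05, 0.5), seed=0,
                       gp_jitter: float = 0.05):
    """Simulate hard genotypes and genotype-probability triplets.

    Per-variant MAF ~ Uniform(maf_range); hard calls ~ Binomial(2, MAF);
    GP triplets are a (1 - jitter) mixture of the hard-call one-hot vector
    with a symmetric Dirichlet(1,1,1) draw, so each triplet sums to one
    exactly; dosage is recomputed as P(0/1) + 2 P(1/1).

    Returns ``(dosages, gp_triplets, mafs)``.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie in (0, 0.5]")
    if not (0 <= gp_jitter < 1):
        raise ValueError("gp_jitter must lie in [0, 1)")
    rng = _rng(seed)
    mafs = rng.uniform(lo, hi, size=m)
    hard = rng.binomial(2, mafs[None, :], size=(n, m))
    onehot = np.eye(3)[hard]                          # n x m x 3
    if gp_jitter > 0:
        g = rng.gamma(1.0, 1.0, size=(n, m, 3))
        dirich = g / g.sum(axis=2, keepdims=True)
        gp = (1.0 - gp_jitter) * onehot + gp_jitter * dirich
    else:
        gp = onehot
    dosages = gp[:, :, 1] + 2.0 * gp[:, :, 2]
    return dosages, gp, mafs


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full cohort under the configured causal structure."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_samples, cfg.n_variants

    dosages, gp, mafs = simulate_genotypes(
        n, m, cfg.maf_range, rng, gp_jitter=cfg.gp_jitter)
    sd = dosages.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    G_std = (dosages - dosages.mean(axis=0)) / sd

    # polygenic signal on X, variance h2 in expectation
    beta_g = rng.normal(0.0, math.sqrt(cfg.h2_instrument / m), size=m) \
        if cfg.h2_instrument > 0 else np.zeros(m)
    P = G_std @ beta_g

    U = rng.standard_normal(n)
    age = rng.normal(55.0, 8.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    agec = (age - age.mean()) / age.std()
    age2c = agec**2 - (agec**2).mean()
    age2c /= age2c.std()
    sexc = sex - sex.mean()
    sexc_sd = sexc.std() if sexc.std() > 0 else 1.0

    groups = cfg.n_covariates
    cols, labels = [], []
    for group, prefix in (("outcome_linked", "wa"), ("exposure_linked", "wb"),
                          ("null", "wn")):
        for j in range(groups.get(group, 0)):
            cols.append(rng.standard_normal(n))
            labels.append(f"{prefix}{j + 1}")
    W = pd.DataFrame(dict(zip(labels, cols))) if cols else pd.DataFrame(index=range(n))
    wa_cols = [c for c in W.columns if c.startswith("wa")]
    wb_cols = [c for c in W.columns if c.startswith("wb")]

    delta_x, delta_y = cfg.confounder_strengths
    eps_x_var = 1.0 - cfg._explained_x
    x0 = (P
          + _WB_LOADING * (W[wb_cols].to_numpy().sum(axis=1) if wb_cols else 0.0)
          + delta_x * U
          + _AGE_LOADING * agec + _AGE2_LOADING * age2c
          + _SEX_LOADING * sexc / sexc_sd
          + rng.normal(0.0, math.sqrt(eps_x_var), size=n))

    dp = cfg.depth_params
    X = dp.mtcn_location + dp.mtcn_scale * x0

    Y = (cfg.theta * X
         + _WA_LOADING * (W[wa_cols].to_numpy().sum(axis=1) if wa_cols else 0.0)
         + delta_y * U
         + rng.normal(0.0, _EPS_Y_SD, size=n))

    batch_idx = rng.integers(0, len(cfg.batch_offsets), size=n)
    batch = np.array([f"batch{i + 1}" for i in batch_idx])
    raw_mtcn = np.exp(X) + np.asarray(cfg.batch_offsets)[batch_idx]
    if np.any(raw_mtcn <= 0):
        raise ValueError("batch offsets drove raw MT-CN nonpositive")

    # composition factor: genetic share kappa through the polygenic signal
    kappa = cfg.composition_loading
    p_sd = P.std()
    p_std = P / p_sd if p_sd > 0 else np.zeros(n)
    C = kappa * p_std + math.sqrt(1.0 - kappa**2) * rng.standard_normal(n)

    neut_lat = _NEUT_LOADING * C + math.sqrt(1 - _NEUT_LOADING**2) * rng.standard_normal(n)
    plt_lat = _PLT_LOADING * C + math.sqrt(1 - _PLT_LOADING**2) * rng.standard_normal(n)
    neutrophil = np.exp(math.log(3.5) + 0.30 * neut_lat)
    lymphocyte = np.exp(math.log(2.0) + 0.25 * rng.standard_normal(n))
    monocyte = np.exp(math.log(0.5) + 0.30 * rng.standard_normal(n))
    leukocyte = neutrophil + lymphocyte + monocyte
    platelet = np.exp(math.log(250.0) + 0.20 * plt_lat)
    cell_counts = pd.DataFrame({
        "leukocyte": leukocyte,
        "neutrophil": neutrophil,
        "lymphocyte_pct": 100.0 * lymphocyte / leukocyte,
        "monocyte": monocyte,
        "platelet": platelet,
    })

    # MAR missingness: probability depends on observed age and sex only
    pheno_cols = ["Y", *W.columns]
    if cfg.missing_rate > 0:
        base = math.log(cfg.missing_rate / (1.0 - cfg.missing_rate))
        logit = base + 0.4 * agec + 0.2 * (sex - 0.5)
        pmiss = 1.0 / (1.0 + np.exp(-logit))
        mask = rng.random((n, len(pheno_cols))) < pmiss[:, None]
    else:
        mask = np.zeros((n, len(pheno_cols)), dtype=bool)
    missing_mask = pd.DataFrame(mask, columns=pheno_cols)

    truth = {
        "theta": cfg.theta,
        "beta_g": beta_g.tolist(),
        "h2_instrument": cfg.h2_instrument,
        "delta_x": delta_x,
        "delta_y": delta_y,
        "wa_loading": _WA_LOADING,
        "wb_loading": _WB_LOADING,
        "age_loadings": [_AGE_LOADING, _AGE2_LOADING],
        "sex_loading": _SEX_LOADING,
        "eps_x_var": eps_x_var,
        "eps_y_sd": _EPS_Y_SD,
        "composition_loading": kappa,
        "batch_offsets": list(cfg.batch_offsets),
        "mtcn_location": dp.mtcn_location,
        "mtcn_scale": dp.mtcn_scale,
        "seed": cfg.seed,
    }

    return SyntheticCohort(
        config=cfg,
        sample_ids=[f"S{i:06d}" for i in range(n)],
        variant_ids=[f"var{j + 1}" for j in range(m)],
        dosages=dosages,
        gp_triplets=gp,
        mafs=mafs,
        W=W,
        U=U,
        X=X,
        Y=Y,
        age=age,
        sex=sex,
        batch=batch,
        raw_mtcn=raw_mtcn,
        cell_counts=cell_counts,
        missing_mask=missing_mask,
        truth=truth,
    )


def wes_capture_profile(length: int, peakedness: float,
                        probe_period: int = 120) -> np.ndarray:
    """Raised-cosine probe-peak train, normalized to mean ~1.

    ``peakedness`` 0 gives the uniform (WGS-like) profile; 1 gives peaks
    that dip to zero between probes.
    """
    b = np.arange(length)
    prof = 1.0 + peakedness * np.cos(2.0 * np.pi * b / probe_period)
    return prof / prof.mean()


def simulate_coverage(true_mtcn, depth_params: DepthParams, mode: str = "wgs",
                      seed=0, sample_ids=None):
    """Per-base Poisson depth on the mitochondrial contig.

    Depth at base b ~ Poisson((MT-CN/2) * haploid coverage * profile(b)),
    with the per-sample haploid autosomal coverage carrying a small
    mean-one lognormal jitter (and being reported alongside, as an
    aligner-based estimate would be).

    Returns ``(summary, profiles)`` where ``summary`` is a DataFrame with
    columns (sample_id, mean_mt_depth, max_mt_depth,
    haploid_autosomal_coverage) and ``profiles`` the n x L depth matrix.
    """
    if mode not in ("wgs", "wes"):
        raise ValueError("mode must be 'wgs' or 'wes'")
    dp = depth_params
    mtcn = np.asarray(true_mtcn, dtype=float).ravel()
    if np.any(mtcn <= 0):
        raise ValueError("true MT-CN must be positive")
    rng = _rng(seed)
    n, L = mtcn.size, dp.mt_genome_length
    s = dp.hapcov_jitter_sd
    hapcov = dp.haploid_autosomal_coverage * np.exp(
        rng.normal(-0.5 * s * s, s, size=n))
    if mode == "wes" and dp.wes_profile_peakedness > 0:
        profile = wes_capture_profile(L, dp.wes_profile_peakedness)
    else:
        profile = np.ones(L)
    lam = (mtcn / 2.0 * hapcov)[:, None] * profile[None, :]
    profiles = rng.poisson(lam).astype(np.int32)
    if sample_ids is None:
        sample_ids = [f"S{i:06d}" for i in range(n)]
    summary = pd.DataFrame({
        "sample_id": sample_ids,
        "mean_mt_depth": profiles.mean(axis=1),
        "max_mt_depth": profiles.max(axis=1),
        "haploid_autosomal_coverage": hapcov,
    })
    return summary, profiles


def coverage_for_cohort(cohort: SyntheticCohort, mode: str = "wgs", seed=0,
                        samples: slice | None = None):
    """Coverage simulation for (a slice of) a cohort's true copy numbers."""
    sl = samples if samples is not None else slice(None)
    return simulate_coverage(np.exp(cohort.X[sl]), cohort.config.depth_params,
                             mode=mode, seed=seed,
                             sample_ids=list(np.asarray(cohort.sample_ids)[sl]))
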