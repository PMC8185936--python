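"""Mitochondrial genome copy number (MT-CN) from sequencing coverage.

Raw MT-CN is twice the ratio of mitochondrial depth to haploid autosomal
coverage: the mean mitochondrial depth is used for whole-genome data
(uniform coverage), the maximum depth for exome data (hybrid-capture
probes make mitochondrial coverage strongly nonuniform, and the peak
depth tracks copy number better than the mean there).

The analysis phenotype is produced by a two-stage normalization: within
each acquisition batch the raw values are residualized on age, age^2 and
(when both sexes are present) sex and inverse-normal transformed; the
batches are then pooled and inverse-normal transformed again.  The result
depends only on within-batch ranks, so additive batch shifts and any
monotone within-batch distortion are removed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import fit_linear, inverse_rank_normal

__all__ = [
    "CoverageSummary",
    "read_depth_table",
    "coverage_summary_from_depths",
    "mtcn_wgs",
    "mtcn_wes",
    "normalize_mtcn",
    "estimator_concordance",
]


@dataclass
class CoverageSummary:
    """Per-sample depth statistics; fields may be scalars or aligned arrays."""

    sample_id: object
    mean_mt_depth: object
    max_mt_depth: object
    haploid_autosomal_coverage: object

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean_mt_depth, dtype=float)
        mx = np.asarray(self.max_mt_depth, dtype=float)
        hap = np.asarray(self.haploid_autosomal_coverage, dtype=float)
        if np.any(mean < 0) or np.any(mx < mean):
            raise ValueError("need max_mt_depth >= mean_mt_depth >= 0")
        if np.any(hap <= 0):
            raise ValueError("haploid autosomal coverage must be positive")


def read_depth_table(path, contig_filter: str, contig_length: int = 16569) -> np.ndarray:
    """Read a samtools-depth style TSV into a dense per-base depth vector.

    Input columns are (contig, 1-based position, depth); positions absent
    from the table are depth 0.
    """
    tab = pd.read_csv(path, sep="\t", header=None,
                      names=["contig", "pos", "depth"],
                      dtype={"contig": str})
    tab = tab[tab["contig"] == contig_filter]
    try:
        pos = tab["pos"].astype(int).to_numpy()
        depth = tab["depth"].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric position/depth in {path}") from exc
    if not np.all(np.isfinite(depth)):
        raise ValueError(f"non-numeric depth in {path}")
    if np.any((pos < 1) | (pos > contig_length)):
        raise ValueError(
            f"positions outside 1..{contig_length} for contig {contig_filter}")
    dense = np.zeros(contig_length)
    dense[pos - 1] = depth
    return dense


def coverage_summary_from_depths(sample_id, depths, haploid_autosomal_coverage
                                 ) -> CoverageSummary:
    d = np.asarray(depths, dtype=float)
    return CoverageSummary(sample_id, float(d.mean()), float(d.max()),
                           float(haploid_autosomal_coverage))


def mtcn_wgs(cs: CoverageSummary):
    """Raw MT-CN from WGS: 2 * mean mtDNA coverage / haploid autosomal coverage."""
    return 2.0 * np.asarray(cs.mean_mt_depth, dtype=float) / \
        np.asarray(cs.haploid_autosomal_coverage, dtype=float)


def mtcn_wes(cs: CoverageSummary):
    """Raw MT-CN from WES: 2 * maximum mtDNA coverage / haploid autosomal coverage."""
    return 2.0 * np.asarray(cs.max_mt_depth, dtype=float) / \
        np.asarray(cs.haploid_autosomal_coverage, dtype=float)


def _batch_design(sub: pd.DataFrame) -> np.ndarray:
    cols = [np.ones(len(sub))]
    if "age" in sub and sub["age"].notna().all():
        age = sub["age"].to_numpy(dtype=float)
        agec = age - age.mean()
        if agec.std() > 0:
            cols.extend([agec, agec**2])
    if "sex" in sub and sub["sex"].notna().all():
        sex = pd.factorize(sub["sex"])[0].astype(float)
        if np.unique(sex).size == 2:   # include sex only when both present
            cols.append(sex - sex.mean())
    return np.column_stack(cols)


def normalize_mtcn(records: pd.DataFrame) -> pd.DataFrame:
    """Batch-wise residualize + double inverse-normal normalization.

    ``records`` needs columns (sample_id, raw_mtcn, batch) and optionally
    age and sex.  Within each batch, raw MT-CN is residualized on the
    available covariates among {age, age^2, sex} and inverse-normal
    transformed; the per-batch transforms are pooled and inverse-normal
    transformed once more.  Returns a copy with ``normalized_mtcn`` filled.
    """
    req = {"sample_id", "raw_mtcn", "batch"}
    if not req.issubset(records.columns):
        raise ValueError(f"records must contain columns {sorted(req)}")
    if np.any(records["raw_mtcn"].to_numpy(dtype=float) <= 0):
        raise ValueError("raw_mtcn must be positive")
    out = records.copy()
    stage1 = np.full(len(out), np.nan)
    for _, idx in out.groupby("batch").groups.items():
        sub = out.loc[idx]
        design = _batch_design(sub)
        if len(sub) <= design.shape[1]:
            raise ValueError("batch has too few samples for its covariates")
        raw = sub["raw_mtcn"].to_numpy(dtype=float)
        if np.all(raw == raw[0]):
            raise ValueError("all raw values identical within a batch")
        resid = fit_linear(raw, design).residuals
        stage1[out.index.get_indexer(idx)] = inverse_rank_normal(resid)
    out["normalized_mtcn"] = inverse_rank_normal(stage1)
    return out


def estimator_concordance(wgs_values, wes_values) -> float:
    """Squared Pearson correlation between paired WGS and WES estimates."""
    a = np.asarray(wgs_values, dtype=float).ravel()
    b = np.asarray(wes_values, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("paired vectors must have equal length")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance input")
    return float(np.corrcoef(a, b)[0, 1] ** 2)
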