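"""Plain-text fixture round trips for synthetic cohorts.

TSV carries matrices at full double precision (%.17g, bit-lossless round
trip); genotypes are additionally written as a minimal VCF 4.2 with
GT:GP:DS FORMAT fields (read back via cyvcf2 at printed precision);
the configuration goes to YAML and the generative truth record to JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import CohortConfig, SyntheticCohort
from .prs import hard_call

__all__ = ["write_fixtures", "read_fixtures", "write_vcf", "read_vcf",
           "write_depth_tsv"]

_FLOAT = "%.17g"


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        obj = dataclasses.asdict(obj)
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_vcf(path, variant_ids, gp_triplets, sample_ids) -> None:
    """Minimal VCF 4.2 with GT:GP:DS, one pseudo-position per variant."""
    gp = np.asarray(gp_triplets, dtype=float)
    ds = gp[:, :, 1] + 2.0 * gp[:, :, 2]
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    calls = hard_call(np.clip(ds, 0, 2))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=1,length={len(variant_ids) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GP,Number=G,Type=Float,'
                 'Description="Genotype probabilities">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Expected alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, sample_ids)) + "\n")
        for j, vid in enumerate(variant_ids):
            fields = ["1", str(j + 1), str(vid), "A", "G", ".", "PASS", ".",
                      "GT:GP:DS"]
            for i in range(gp.shape[0]):
                trip = ",".join(f"{x:.6g}" for x in gp[i, j])
                fields.append(f"{gt_codes[int(calls[i, j])]}:{trip}:{ds[i, j]:.6g}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path):
    """Read GP and DS back from a VCF; returns (variant_ids, gp, ds)."""
    from cyvcf2 import VCF

    ids, gps, dss = [], [], []
    for rec in VCF(str(path)):
        ids.append(rec.ID)
        gps.append(np.asarray(rec.format("GP"), dtype=float))
        dss.append(np.asarray(rec.format("DS"), dtype=float).ravel())
    gp = np.stack(gps, axis=1)    # n x m x 3
    ds = np.stack(dss, axis=1)    # n x m
    return ids, gp, ds


def write_depth_tsv(path, contig: str, depths) -> None:
    """samtools-depth style TSV: contig, 1-based position, depth."""
    d = np.asarray(depths)
    pd.DataFrame({"contig": contig, "pos": np.arange(1, d.size + 1),
                  "depth": d}).to_csv(path, sep="\t", header=False, index=False)


def write_fixtures(cohort: SyntheticCohort, directory) -> Path:
    """Write every cohort field to plain-text files under ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    ids = cohort.sample_ids

    pd.DataFrame(cohort.dosages, index=ids, columns=cohort.variant_ids) \
        .rename_axis("sample_id").to_csv(d / "dosages.tsv", sep="\t",
                                         float_format=_FLOAT)
    n, m, _ = cohort.gp_triplets.shape
    gp_cols = [f"{v}_gp{k}" for v in cohort.variant_ids for k in range(3)]
    pd.DataFrame(cohort.gp_triplets.reshape(n, m * 3), index=ids,
                 columns=gp_cols).rename_axis("sample_id") \
        .to_csv(d / "gp.tsv", sep="\t", float_format=_FLOAT)
    pd.DataFrame({"variant_id": cohort.variant_ids, "maf": cohort.mafs}) \
        .to_csv(d / "mafs.tsv", sep="\t", index=False, float_format=_FLOAT)

    W = cohort.W.copy()
    W.insert(0, "sample_id", ids)
    W.to_csv(d / "covariates.tsv", sep="\t", index=False, float_format=_FLOAT)

    pd.DataFrame({"sample_id": ids, "X": cohort.X, "Y": cohort.Y,
                  "U": cohort.U, "age": cohort.age, "sex": cohort.sex,
                  "batch": cohort.batch, "raw_mtcn": cohort.raw_mtcn}) \
        .to_csv(d / "phenotypes.tsv", sep="\t", index=False,
                float_format=_FLOAT, na_rep="NA")

    cc = cohort.cell_counts.copy()
    cc.insert(0, "sample_id", ids)
    cc.to_csv(d / "cell_counts.tsv", sep="\t", index=False, float_format=_FLOAT)

    mask = cohort.missing_mask.astype(int).copy()
    mask.insert(0, "sample_id", ids)
    mask.to_csv(d / "missing_mask.tsv", sep="\t", index=False)

    with open(d / "truth.json", "w") as fh:
        json.dump(_to_plain(cohort.truth), fh, indent=1)
    with open(d / "config.yaml", "w") as fh:
        yaml.safe_dump(_to_plain(cohort.config), fh)

    write_vcf(d / "genotypes.vcf", cohort.variant_ids, cohort.gp_triplets, ids)
    return d


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        tab = pd.read_csv(path, sep="\t", **kw)
    except Exception as exc:
        raise ValueError(f"failed to parse {path}: {exc}") from exc
    if tab.empty:
        raise ValueError(f"failed to parse {path}: no rows")
    return tab


def read_fixtures(directory) -> SyntheticCohort:
    """Reconstruct a cohort from :func:`write_fixtures` output."""
    d = Path(directory)
    try:
        with open(d / "config.yaml") as fh:
            config = CohortConfig(**yaml.safe_load(fh))
        with open(d / "truth.json") as fh:
            truth = json.load(fh)
    except (OSError, TypeError, ValueError, yaml.YAMLError) as exc:
        raise ValueError(f"failed to parse config/truth in {d}: {exc}") from exc

    dos = _read_tsv(d / "dosages.tsv", index_col="sample_id")
    ids = dos.index.tolist()
    variant_ids = dos.columns.tolist()
    gp_tab = _read_tsv(d / "gp.tsv", index_col="sample_id")
    n, m = dos.shape
    if gp_tab.shape != (n, 3 * m):
        raise ValueError(f"failed to parse {d / 'gp.tsv'}: wrong shape "
                         f"{gp_tab.shape}, expected {(n, 3 * m)}")
    gp = gp_tab.to_numpy(dtype=float).reshape(n, m, 3)
    mafs = _read_tsv(d / "mafs.tsv")["maf"].to_numpy(dtype=float)

    W = _read_tsv(d / "covariates.tsv").drop(columns="sample_id") \
        if (d / "covariates.tsv").exists() else pd.DataFrame(index=range(n))
    ph = _read_tsv(d / "phenotypes.tsv", na_values="NA")
    cc = _read_tsv(d / "cell_counts.tsv").drop(columns="sample_id")
    mask = _read_tsv(d / "missing_mask.tsv").drop(columns="sample_id") \
        .astype(bool)

    return SyntheticCohort(
        config=config, sample_ids=ids, variant_ids=variant_ids,
        dosages=dos.to_numpy(dtype=float), gp_triplets=gp, mafs=mafs,
        W=W, U=ph["U"].to_numpy(dtype=float), X=ph["X"].to_numpy(dtype=float),
        Y=ph["Y"].to_numpy(dtype=float), age=ph["age"].to_numpy(dtype=float),
        sex=ph["sex"].to_numpy(dtype=float), batch=ph["batch"].to_numpy(),
        raw_mtcn=ph["raw_mtcn"].to_numpy(dtype=float), cell_counts=cc,
        missing_mask=mask, truth=truth)
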