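# mitomr

Tools for linking blood-derived **mitochondrial genome copy number
(MT-CN)** to metabolic traits: coverage-based MT-CN estimation, a
penalized multi-variant **Mendelian randomization** causality test,
polygenic-score replication with blood-cell-count adjustment, and a
phenome-wide screen with false-discovery control.  A synthetic cohort
generator reproduces the statistical structure the analyses assume, so
the whole chain is testable without access-controlled cohort data.

Intended users: statistical geneticists and biostatisticians who want
either the individual building blocks (rank-based inverse normal
transform, Rubin pooling, IVW/DerSimonian–Laird meta-analysis, Storey
q-values, penalized regression with an unpenalized covariate block) or
the assembled pipeline.

## The model

MT-CN is estimated from sequencing depth as twice the mitochondrial :
autosomal coverage ratio — `2·mean(mt depth)/haploid coverage` for WGS,
`2·max(mt depth)/haploid coverage` for WES (capture probes make exome
mitochondrial coverage peaked) — then batch-normalized by residualizing
on age, age², sex and applying a rank-based inverse normal transform
within and then across batches.

The causality test instruments X = ln(MT-CN) with an out-of-fold
penalized polygenic predictor: with covariate sets A (outcome-associated)
and B (exposure-associated given A) adjusted without penalty,

    β_G^(−j) = argmin_β ½‖X − Gβ − W_AB γ‖² + λ·pen(β),   j = 1…5,
    Z_i = G_i · β_G^(−fold(i)),

and a significant coefficient of Z in the regression of Y = ln(insulin)
on Z (adjusted for covariates with first-order associations with Z or Y)
is evidence that X is causal for Y.  Missing phenotypes are multiply
imputed (chained regression trees); estimates are pooled by Rubin's
rules (t test, m − 2 df) and combined across datasets by
inverse-variance weighted meta-analysis (Z test).  The averaged weights
β̄_G projected onto hard-called dosages of an independent cohort form a
polygenic score whose cell-count and metabolic-trait associations —
with and without neutrophil/platelet adjustment — probe whether the
MT-CN signal is mediated by blood composition.

See `docs/methods.md` for assumptions, parameter defaults, and known
limitations.

## Worked example

`examples/` contains one narrative script per capability.  Running
`python examples/03_mendelian_randomization.py` simulates a cohort of
2500 samples with a true causal effect θ = 0.15 of ln(MT-CN) on
ln(insulin) and prints:

```
true causal effect of ln(MT-CN) on ln(insulin): 0.15
L1: pooled beta +0.298 (se 0.114, t-test with 8 df, p 0.031); instrument-exposure corr 0.41
    meta (single dataset, Z test): beta +0.298, p 0.009
L2: pooled beta +0.381 (se 0.124, t-test with 8 df, p 0.015); instrument-exposure corr 0.43
    meta (single dataset, Z test): beta +0.381, p 0.002
post hoc high-leverage/high-residual exclusions: 32
L2 pooled beta after exclusion: +0.365 (a stable estimate means the result is not outlier-driven)
```

Both penalties recover an estimate consistent with θ (within about two
pooled standard errors), agree with each other, and survive the post hoc
outlier rerun — the three robustness signatures the method is built
around.  The other examples cover cohort simulation and fixture I/O
(`01`), coverage-based MT-CN estimation and normalization (`02`), the
polygenic-score mediation analysis (`04`), and the phenome screen
(`05`).

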