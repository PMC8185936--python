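# Methods

`mitomr` implements a computational chain linking blood-derived
mitochondrial genome copy number (MT-CN) to metabolic traits: coverage
ratio estimation of MT-CN, a penalized multi-variant Mendelian
randomization (MR) causality test of MT-CN on fasting insulin, a
polygenic-score replication workflow with blood-cell-count adjustment,
and a phenome-wide screen with false-discovery control.  Every stage is
exercisable on a synthetic cohort generator that reproduces the
statistical structure the analyses assume, so no access-controlled data
are needed to test the machinery.

## Copy-number estimation and normalization

Raw MT-CN is twice the ratio of mitochondrial sequencing depth to the
haploid autosomal coverage:

    MT-CN_WGS = 2 * mean mtDNA depth / haploid autosomal coverage
    MT-CN_WES = 2 * max  mtDNA depth / haploid autosomal coverage

Whole-genome coverage of the mitochondrial contig is close to uniform,
so its mean tracks copy number.  Exome capture makes mitochondrial
coverage strongly peaked around probes; the maximum depth is then a more
stable single-number summary than the mean.  On synthetic data the
choice is reported, not asserted: which summary wins is a property of
the data (probe geometry, off-target rate), not of the code.

The analysis phenotype is produced in two stages.  Within each
acquisition batch, raw values are residualized by ordinary least squares
on age, age², and sex — sex only where the batch actually contains both
sexes, since a single-sex batch would make that column degenerate — and
the residuals are mapped to normal quantiles by the rank-based inverse
normal transform (IRN), Φ⁻¹((r − 0.5)/n) with average ranks for ties.
The per-batch transforms are pooled and IRN is applied once more.
Because each stage depends only on within-batch ranks, additive batch
shifts and any strictly monotone within-batch distortion cancel exactly;
the final phenotype has mean ≈ 0 and variance ≈ 1 by construction.

## The Mendelian randomization procedure

The causality test asks whether X = ln(MT-CN) causes Y = ln(fasting
insulin), using a genetic instrument Z built from many common variants
at once (dosage matrix G, minor-allele-frequency filter 1%):

1. **Covariate partitioning.** Columns of the covariate matrix W whose
   marginal linear association with Y passes the screening threshold
   form set A; remaining columns associated with X conditional on A form
   set B.  The screening threshold defaults to the Bonferroni level
   0.05 / #covariates — conservative inclusion limits false covariates
   in the instrument regression.
2. **Instrument construction.** X is regressed on G with an L1 or L2
   penalty; A ∪ B (plus an intercept) enter as an unpenalized free
   block.  Samples are split into K = 5 folds; fold j's weights
   β_G^(−j) are fit without fold j, and each sample receives
   Z_i = G_i · β_G^(−fold(i)).  The penalty weight λ is chosen per fold
   by inner 5-fold cross-validation with the one-standard-error rule.
   Out-of-fold prediction prevents the instrument from absorbing the
   noise of X, which would otherwise bias the causality test; the λ
   choice keeps Z approximately calibrated for X (regression slope of X
   on Z ≈ 1), which is what makes the Z-coefficient of the causality
   regression interpretable as the causal effect of X.
3. **Causality-test adjustment.** Each covariate is classified by
   first-order association with Z and with Y into sets I (neither),
   II (both), III (Z only), IV (Y only); II ∪ III ∪ IV are adjusted in
   the OLS of Y on Z.  Set I is never adjusted.
4. **Multiple imputation.** Missing phenotype entries are imputed by
   chained equations (default learner: depth-5 regression trees with
   imputations drawn from terminal-node donors, so imputed values are
   always observed values; Gaussian Bayesian-regression fallback),
   25 sweeps by default.  The imputation model always includes the
   exposure X and the missingness drivers age and sex as complete
   predictor columns: leaving them out is uncongenial with the
   missing-at-random mechanism and measurably attenuates and
   de-calibrates the final test.  The entire chain (partitioning,
   instrument, classification, causality regression) is re-run inside
   every completed data set.
5. **Pooling and meta-analysis.** Per-imputation estimates are combined
   with Rubin's rules, T = W̄ + (1 + 1/m)·B, and referred to a t
   distribution with m − 2 degrees of freedom (so m = 1000 imputations
   give a t with 998 df; the Barnard–Rubin adjusted df is available as
   an option).  Datasets are pooled by fixed-effect inverse-variance
   weighted meta-analysis with a Z test; DerSimonian–Laird
   random-effects pooling is also provided.

**Fold reuse across imputations.** The fold assignment is drawn once per
dataset and shared by all imputation replicates.  The instrument is
still rebuilt on every completed table, but re-randomizing the folds
each time would add fold-resampling Monte Carlo noise to Rubin's
between-imputation variance — which treats all between-replicate spread
as imputation uncertainty — and makes the pooled test badly
conservative (empirically, type-I error 0.005 at nominal 0.05).

**Known residual conservatism.** Even with complete data the causality
test is slightly conservative (empirical type-I ≈ 0.03 at nominal 0.05
in the null calibration below).  This is a property of split-sample
instruments under exposure confounding: each sample's exposure noise
enters the fold weights that generate *other* samples' Z values,
creating small cross-sample score correlations that the conventional
OLS variance ignores, in the conservative direction.

**Outlier handling.** Before analysis, samples that are multivariate
outliers of the quantitative-trait matrix (iterated PCA trimming at 6
SD plus Mahalanobis distance beyond the χ² 10⁻⁶ tail) are removed.
Post hoc, every sample that was ever among the ten highest-leverage
points with standardized residual above one in any imputation's
causality regression is excluded and the whole analysis re-run; a
stable estimate indicates the result is not outlier-driven.

## Polygenic-score replication

The instrument weights averaged over folds (and, in a full run, over
imputation replicates), β̄_G, act as a polygenic risk score in an
independent cohort: genotype-probability triplets collapse to expected
dosage DS = P(0/1) + 2·P(1/1), hard calls use thresholds 0.5 and 1.5
(boundary assigned upward), and Z̃ = G̃ · β̄_G with alignment strictly by
variant id (unmatched ids are a hard error).  Cell-count traits are
log-transformed and standardized within sex; the lymphocyte count is
the product of leukocyte count and lymphocyte fraction (auto-rescaled
when given as a percentage).  Associations use

    trait ~ PRS + Age + Age² + Sex + Age:Sex + Age²:Sex + PCs

optionally plus neutrophil and platelet counts.  The attenuation of a
metabolic-trait association under that adjustment is the mediation
signature: it indicates the score's metabolic signal travels through
blood cell composition.  Outliers are removed by up to three iterations
of PCA trimming of the cell-count matrix (6 SD) and up to two rounds of
null-model leverage/residual screening (|standardized residual| > 6, or
leverage > 3p/n with |standardized residual| > 2).  These cutoffs are
declared defaults of this package, conservative under normal theory,
and configurable.

## Phenome screen

Phenotype curation emits every continuous variable twice (raw and IRN),
keeps binary variables, splits unordered categorical variables into
one-vs-rest indicators tested by logistic regression, and excludes
sex-specific (or nearly sex-specific, >98% one sex among carriers)
categorical traits and constant columns, each with a recorded reason.
q-values apply the Benjamini–Hochberg procedure scaled by Storey's
estimated null proportion π₀ (λ-grid 0.05…0.95, cubic polynomial
smoother evaluated at λ = 0.95, clipped to (0, 1]; π₀ = 1 reduces
exactly to BH).  The primary q-family pools categorical/binary tests
with the IRN continuous versions; the secondary family uses the raw
versions.  Interpreting the IRN family is the conservative,
outlier-robust choice; the raw family is reported alongside.

## The synthetic cohort generator

`simulate_cohort` draws per-variant MAF ~ Uniform(0.05, 0.5), hard
genotypes ~ Binomial(2, MAF), and genotype-probability triplets as a
95/5 mixture of the one-hot hard call with a symmetric Dirichlet draw
(dosage is recomputed from the triplet, so DS = P(0/1) + 2·P(1/1) holds
for every entry).  On a standardized latent scale, the exposure is

    X₀ = G·β_G + 0.1·ΣW_B + δ_X·U + age/sex terms + ε_X,

with β_G ~ N(0, h²/m) on standardized genotypes (defaults h² = 0.2,
δ_X = 0.3, age+age² contributing 2% of variance and sex 1%), and
X = ln(MT-CN) = 5.3 + 0.25·X₀, i.e. copy number ≈ 200 with ≈ 25%
coefficient of variation — the scale of blood-derived measurements.
The outcome is Y = θ·X + 0.3·ΣW_A + δ_Y·U + ε_Y (ε_Y sd 0.4), U being
the latent confounder.  Batch mean shifts (0, +15, −10) act on the raw
copy-number scale.  Missingness is missing-at-random: a logistic
function of observed age and sex only, default rate 5%, applied to Y
and the covariates.  Sequencing depth is Poisson with mean
(MT-CN/2) × haploid coverage × profile(b), profile ≡ 1 for WGS and a
raised-cosine probe train (period 120 bp, peakedness 0.9) for WES, with
a 5% lognormal jitter on per-sample haploid coverage.

A single composition factor C = κ·(standardized polygenic signal of X)
+ √(1−κ²)·noise couples the genetics of the exposure to neutrophil
(loading 0.8) and platelet (0.7) counts; κ defaults to 0.5.  With
κ > 0 the polygenic score's path to the outcome is partially proxied by
neutrophil/platelet counts, so cell-count adjustment attenuates the
PRS–trait association — the qualitative mediation finding the
replication workflow is designed to detect; κ = 0 switches it off.  How
much of real blood MT-CN variance is compositional versus intracellular
is not something these simulations estimate; κ is a free structural
parameter.

What the generator does *not* emulate: linkage disequilibrium between
variants (the MR method does not require it), relatedness and
population structure, sequence-level artifacts (NUMT mis-mapping,
reference bias), genotype-imputation error structure, and non-random
(MNAR) missingness.  Passing tests therefore demonstrate the
statistical machinery under its stated assumptions, not robustness to
these real-data complications.

## Problem sizes used by the test suite and acceptance script

Chosen to give informative checks at interactive runtimes on one CPU:

- causal-effect recovery: n = 4000, 100 variants, h² = 0.2, θ = 0.15,
  20 imputations (tree learner, 5 sweeps), both penalties; the pooled
  estimate must land within 2 pooled SEs of θ and the two penalties
  within 1.5 combined SEs of each other;
- null calibration: 200 replicates of n = 2000, θ = 0, 10 imputations
  (Gaussian learner, 5 sweeps), L2 penalty; empirical type-I at
  α = 0.05 must lie in [0.02, 0.09];
- copy-number recovery: 100 WGS samples at true MT-CN 200, haploid
  coverage 20; mean estimate within 1% of truth;
- mediation: n = 4000, θ = 0.4, κ = 0.8 (power to resolve a strict
  |t| decrease in a single cohort) versus κ = 0;
- screen null calibration: 100 replicates of 200 all-null traits
  (160 continuous + 40 binary) at n = 2000; at least 90% must leave
  every primary-family q above 0.05.

MI sweep counts below the default 25 in these runs are a scaling
choice; with only one phenotype block missing at 5%, the chains mix in
a few sweeps.

## Numerical choices

- OLS via thin QR; leverage is the row-sum of squares of Q; rank
  deficiency raises rather than silently dropping columns.
- Logistic fits by IRLS from a zero start, convergence at 1e-10;
  separation is declared when any coefficient exceeds 15 on the
  standardized design.
- The penalized solver works on the Gram matrix of the standardized,
  free-block-residualized penalized columns (Frisch–Waugh partialling is
  exact for an unpenalized block under either penalty): L1 by cyclic
  coordinate descent with covariance updates (tolerance 1e-7, at most
  1e5 sweeps, warm starts along the λ path), L2 in closed form (an
  eigendecomposition serves the whole λ grid during cross-validation).
  Penalized columns are standardized to unit variance internally and
  coefficients returned on the original scale, making λ comparable
  across variants; `standardize=False` is available for analyses posed
  on a fixed design scale.
- λ grids: L1 from λ_max = max|P̃ᵀỹ| down three decades; L2 spans
  n × [10⁻³, 10³], 25 points, both log-spaced.
- Hard-call boundaries (0.5, 1.5) assign upward; boundary mass is
  negligible for continuous dosages.
- IRN uses the (r − 0.5)/n offset; all-identical input is degenerate
  and returns the median quantile with a warning.
- TSV fixtures print floats at %.17g (bit-lossless round trip); the
  VCF 4.2 path (GT:GP:DS) round-trips at its printed precision.
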