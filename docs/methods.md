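# Methods

## The statistical problem

The package predicts per-cow blood-metabolite concentrations from milk FTIR
spectra, optionally augmented with on-farm class covariates (days in milk,
parity) and SNP genotypes, and estimates the genetic architecture of those
metabolites with a single-step genomic animal model.  Two prediction engines
are compared — BayesB (sparse Bayesian linear regression) and a tuned
gradient boosting machine — under four nested predictor sets (M1: spectra
only; M2: + on-farm; M3: + SNPs; M4: all) and three cross-validation designs
of increasing train/validation independence (random tenfold, whole-batch
hold-out, whole-herd hold-out).

## Synthetic cohorts

Because the motivating field data are proprietary, a first-class generator
produces cohorts with the same statistical anatomy.

**Population.**  Default 1020 cows in two herds (945/75) sampled in 16
herd/date batches (the second herd receives a proportional share of batches,
at least one), with a 3-generation pedigree (founder sires/dams, an
intermediate breeding generation, then the study cows).  Genotypes are
gene-dropped through the pedigree from founder allele frequencies drawn
Uniform(0.05, 0.5) — the lower edge sits at the MAF filter so genotype QC is
non-trivial.  Offspring alleles are transmitted with probability equal to
half the parental dosage, which is exact for unphased HWE genotypes.

**Phenotypes.**  Per trait,

    y = mu + dim_effect[class] + parity_effect[class] + a + b_batch + e

with `a = Z_c beta` built from a sparse 5% subset of SNPs, batch effects
i.i.d. normal per batch, and fixed DIM/parity class effects equal to a
linear ramp scaled to 0.3 residual SD.  Components are rescaled so the
realized sample ratios hit the targets exactly:
h² = var(a)/(var(a)+var(e)) and h_batch = var(b)/(var(a)+var(b)+var(e)).
The default trait panel spans 15 metabolite-like traits with h² from 0.05 to
0.60 and batch incidences from 0.01 to 0.44, the ranges typical of blood
metabolic indicators in dairy cows.

**Spectra.**  Each cow gets two replicate spectra: a smooth baseline, a
herd-level offset curve, a per-batch drift curve (instrument/date
structure), trait-specific loadings — 10 to 30 Gaussian bands per trait,
emulating chemical-bond absorbance windows — times a noisy standardized copy
of the trait's non-systematic part (a + b + e), and i.i.d. channel and
replicate noise.  `spectral_signal` is the share of that non-systematic
variance recoverable from spectra in the infinite-data limit (the loading
latent is the signal plus independent noise with variance
var(u)(1−s)/s).  When `spectral_signal = 0` the herd/batch spectral
structure is also omitted, so that spectra are then completely uninformative
about the phenotype — otherwise batch membership alone would leak the batch
component of y and break the no-signal null.  Spectra are emitted as
transmittance T = 10^(−A) with A = 0.5 + 0.08·raw (clipped positive), so the
full absorbance-transform path is exercised.  A configurable fraction of
cows receives gross spectral contamination (±12 raw units per channel with
random signs) to exercise outlier QC.

**What the generator does and does not emulate.**  It reproduces the
variance-component layering, herd/batch confounding, band-structured
spectra–trait linkage, replicate structure, and QC-relevant pathologies
(low MAF, missingness, outliers).  It does not model linkage disequilibrium
decay, lactation-curve dynamics beyond DIM class effects, non-linear
spectra–metabolite chemistry, or genotype-by-environment interaction.
Passing tests therefore demonstrate the machinery is correct and the
qualitative orderings hold under the assumed generative model, not that any
particular real-data R² will be attained.

## Spectra preprocessing

Pipeline order is fixed: absorbance (log₁₀(1/T), base 10 per spectroscopy
convention) → per-channel standardization → replicate averaging → outlier
removal.  Standardization uses the sample SD (n−1) everywhere, matching the
regression conventions downstream.  Water-absorption regions are retained;
no derivative or scatter correction is applied — the learners are expected
to tolerate noisy channels.  Outliers are screened in PCA space: the
smallest number of components explaining ≥ 95% of variance (capped at
min(n−1, p); a full-rank Mahalanobis distance is singular when n < p), with
the squared Mahalanobis distance referred to the χ²(k) quantile at 1 − α
(α = 0.05 default).  The χ² reference and the 95% component rule are
documented assumptions — the screening literature specifies only a
significance level.  QC runs once on the full cohort before CV splitting,
matching the data flow of a field study.

## Kinship and genotype QC

Filter order is fixed and reported per step: non-autosomal SNPs → SNP call
rate (< 0.95 removed) → MAF (strictly < 0.05 removed) → Hardy–Weinberg
(P ≤ 10⁻⁵ removed; exact conditional test below 1000 genotypes, 1-df χ²
above) → sample call rate.  Remaining missing dosages are imputed to 2pⱼ,
which preserves allele frequencies.  **G** centers the dosage matrix by 2pⱼ
(observed frequencies) before the quadratic form — an uncentered MM′ is not
a relationship matrix — and is blended 0.95 G + 0.05 A₂₂ before inversion to
guarantee positive definiteness, standard single-step practice.  **A** uses
the tabular recursive method; **H**⁻¹ applies the genotyped-block correction
G_b⁻¹ − A₂₂⁻¹ in A's ordering.  Dense inversion is used throughout; the
package targets cohorts of a few thousand animals, not national evaluations.

## Animal-model Gibbs sampler

Flat priors on fixed effects (intercept + DIM/parity dummies, reference
coding for full rank); scaled-inverse-χ² priors on the three variances with
df = 4 and scales set from the phenotypic variance split ½ residual, ¼
genetic, ¼ batch — a weakly-informative default, configurable.  Location
effects are updated single-site with residual updating (memory-light and
adequate at package scale; the hot loop is numba-compiled); variances from
their conjugate full conditionals.  The chain defaults used by the
high-level fitters are 50 000 cycles / 10 000 burn-in / thin 5; the
full-scale 500 000 / 100 000 / 5 configuration (80 000 stored samples) is
available via `ChainConfig()`.

Heritability is defined as h² = σ²ₐ/(σ²ₐ+σ²ₑ) — the batch variance is
deliberately excluded from the denominator, matching the definition used for
the reference variance-component panel even though a three-component
denominator is more common; batch incidence uses the full denominator.  Both
ratios are computed per stored sample and summarized as the posterior mean
of the ratios (not the ratio of posterior means).  Convergence is assessed
with the Geweke diagnostic, classical segments (first 10% vs last 50%) and a
Bartlett-windowed spectral-density estimate of each segment-mean variance; a
failed check flags the summary but does not raise.

## BayesB

The mixture prior p(w) = π·t(w | df, S_B) + (1−π)·δ₀ is implemented with the
scaled-t slab represented as a normal with per-predictor
scaled-inverse-χ²(df = 5, S_B) variance.  S_B = var(y)·VP·(df+2)/MS_x/π with
VP = 0.5 shared across the concatenated FTIR+SNP block (one mixture, one π;
MS_x is the summed column variance of the concatenated standardized
predictors).  The residual variance has scale S_e = var(y)·R²·(df_e+2) with
R² = 0.5, df_e = 5.  π has a beta prior; the conventional shapes
(π₀·counts, (1−π₀)·counts) drive the update, while the alternative printed
quantity π₀(1−π₀)/(counts+1) is computed by `beta_prior_shapes` and recorded
in the run manifest alongside them, because both parameterizations circulate
for these defaults.  Inclusion indicators are sampled with the effect
integrated out (no trans-dimensional moves; faster mixing), so excluded
effects are exact zeros at every iteration.  On-farm covariates enter as a
flat-prior one-hot block, mirroring their fixed-effect treatment in the
genetic model.  Predictor columns are standardized with training-fold
statistics only — no information crosses CV folds.  Desk default chain:
20 000 / 5 000 / 5.  Degenerate options (`fix_pi`, `common_variance`,
`fix_sigma2`, `fix_sigma2_e`) collapse the sampler onto closed-form special
cases (ridge regression) used as oracles in the tests.

## Gradient boosting

Squared-error stagewise boosting over depth-limited CART regression trees
(sklearn's implementation supplies the trees; the tuning protocol and the
importance statistic are authored here).  Random search samples up to 100
unique configurations from the fixed grid — trees 100–3000 step 20, learning
rate 0–1 step 0.1, depth 5–80 step 5, min leaf 20–100 step 20 — evaluated by
inner 5-fold CV on the training set only; the winner maximizes inner R² with
MSE as tie-break and is refit on the full training set.  A sampled learning
rate of exactly 0 is honored as a guarded mean-predicting model so the grid
is respected without degenerate fits.  Tree depth is capped at ⌈log₂ n⌉
(deeper grids are vacuous at moderate n); the cap is recorded in the
manifest.  On-farm classes enter as ordinal integer features — trees handle
ordinal codes natively.  Row/column subsampling is disabled (not part of the
search space).  Variable importance credits each split's squared weighted
impurity reduction to the splitting feature, summed over all trees and
normalized to percentages summing to 100; wavelengths above a 0.8% threshold
are reported as "significant", with per-trait overlap helpers.

## Cross-validation and statistics

Fold assignments are made once per scheme and consumed identically by both
methods and all four models.  Batch-out validation groups are a documented
reconstruction: each batch's genomic profile is the mean of its cows' rows
of G; batches are ranked by mean Euclidean distance to the other profiles
and chunked, farthest first, into validation groups of three.  With 16
batches and triples, five replicates cannot cover every batch, so the
replicate count is raised automatically until each batch is validated at
least once (the guarantee is "at least once", not "exactly once").  Herd-out
emits both directions as two replicates and reports them individually — a
2-point SD is not meaningful.  R² is the squared Pearson correlation between
observed and predicted values (association; bias is reported separately),
the calibration slope regresses observed on predicted (1 unbiased, > 1
deflated), RMSE is √(Σ(y−ŷ)²/n), and RD = (r_m − r_M1)/r_M1 × 100.
Replicate summaries use the sample SD.

## Desk-scale problem sizes

Simulation-backed checks run at reduced sizes chosen as the package's
default testing scale: variance-component recovery uses cohorts of 400 cows,
300 SNPs and 8 000–10 000-cycle chains; the model/scheme ordering check uses
260-cow cohorts, 50 wavelengths, 150 SNPs, 5 random folds, short BayesB
chains (1 200–1 500 cycles) and a 2-configuration boosting search; the
planted-window recovery check uses 250 cows and 300 wavelengths.  All sizes
appear in the tests and `scripts/acceptance.py` and scale up by
configuration only.

## Known limitations

* Dense linear algebra bounds cohort size (no sparse H⁻¹, APY, or
  metafounders).
* Single-trait models only; no REML alternative to the Gibbs sampler.
* The batch-out selection rule is one reasonable reconstruction of a
  distance-based assignment; it is a seeded, replaceable strategy.
* Simulated spectra are linear in the trait latents; non-linear
  spectra–metabolite relationships (one motivation for boosting) are not
  emulated, so method rankings on synthetic data need not match field data.
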