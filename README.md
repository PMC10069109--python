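# ftirpred

Predicting blood indicators of metabolic disorders in dairy cows from milk
Fourier-transform infrared (FTIR) spectra, integrated with on-farm covariates
(days in milk, parity) and SNP genotypes.

Blood metabolic profiling — glucose, BHBA, urea, liver enzymes (AST, GGT,
PON), oxidative-stress markers (ROMt, AOPP, FRAP), inflammation markers
(ceruloplasmin, total proteins, globulins) and minerals (Ca, K, Zn) — is the
reference method for monitoring metabolic health in dairy herds, but blood
sampling is invasive and expensive at scale.  Milk FTIR spectra (absorbance at
~1060 wavenumbers, 5011–925 cm⁻¹) are cheap, routine, and informative about
the milk-composition changes that accompany metabolic disturbance.  This
package implements a full prediction pipeline for that setting, for
quantitative geneticists and dairy-phenomics researchers:

* **Spectra preprocessing** — absorbance transform *A* = log₁₀(1/*T*),
  per-channel standardization, replicate averaging, and PCA/Mahalanobis
  outlier removal at a chosen significance level.
* **Kinship** — SNP/sample QC (autosomes, call rate ≥ 0.95, MAF ≥ 0.05,
  Hardy–Weinberg exact/χ² test at *P* > 10⁻⁵), the pedigree numerator
  relationship matrix **A**, the genomic relationship matrix
  **G** = **ZZ**′ / 2Σ*p*ⱼ(1−*p*ⱼ) (VanRaden), and the single-step inverse
  **H**⁻¹ = **A**⁻¹ + [0 0; 0 **G**⁻¹ − **A**₂₂⁻¹].
* **Variance components** — a Gibbs sampler for the animal model
  **y** = **Xb** + **Wh** + **Za** + **e** with **a** ~ N(0, **H**σ²ₐ),
  batch effects **h** ~ N(0, **I**σ²_batch), reporting the posterior of
  *h*² = σ²ₐ/(σ²ₐ+σ²ₑ) and batch incidence
  *h*_batch = σ²_batch/(σ²ₐ+σ²_batch+σ²ₑ), with Geweke convergence checks.
* **Prediction** — a from-scratch BayesB sampler (point mass at zero +
  scaled-*t* slab, S_B = var(y)·VP·(df+2)/MS_x/π) and a random-search-tuned
  gradient boosting machine with squared-improvement variable importance,
  each fitted under four nested predictor models: M1 = FTIR only,
  M2 = FTIR + on-farm, M3 = FTIR + SNPs, M4 = all three.
* **Evaluation** — tenfold, batch-out (batches held out by genomic distance
  between batch profiles) and herd-out cross-validation; R² (squared Pearson
  correlation), RMSE, calibration slope, and the relative difference
  RD = (r_m − r_M1)/r_M1 × 100 versus the FTIR-only baseline.
* **Synthetic cohorts** — a generator emulating a two-herd, 16-batch
  population with a 3-generation pedigree, gene-dropped genotypes, and
  spectra that carry a tunable share of each trait's signal, so the entire
  pipeline runs and is tested without any external data.

## Worked example

```python
import ftirpred as fp
from ftirpred.animal_model import ChainConfig
from ftirpred.boosting import GBMSearchSpace
from ftirpred.cv import run_experiment
from ftirpred.io import dim_class, parity_class, prepare_analysis_data

cfg = fp.SimConfig(
    n_cows=300, n_snps=200, n_wavelengths=60, n_batches=8,
    herd_sizes=(240, 60), traits={"glucose": fp.TraitTargets(0.36, 0.44)},
    spectral_signal=0.75, rng_seed=42,
)
bundle = fp.simulate_dataset(cfg)
data, kinship, attrition = prepare_analysis_data(
    bundle.cow_table, bundle.spectra, bundle.genotypes, bundle.pedigree
)
print(f"analysis cows: {attrition['analysis_cows']}, "
      f"SNPs after QC: {attrition['snps_after_qc']}")

cow = bundle.cow_table.copy()
cow["dim_class"] = dim_class(cow["dim"])
cow["parity_class"] = parity_class(cow["parity"])
summary = fp.gibbs_animal_model(
    cow, kinship, "glucose",
    chain=ChainConfig(n_iter=10_000, burn_in=2_000, thin=5, seed=42),
)
print(f"h2 = {summary.h2_mean:.3f} +/- {summary.h2_sd:.3f}, "
      f"h_batch = {summary.hbatch_mean:.3f} +/- {summary.hbatch_sd:.3f}")

result = run_experiment(
    data, models=("M1", "M4"), schemes=("tenfold", "herd_out"), seed=42,
    bayesb_params=dict(n_iter=1500, burn_in=500, thin=2),
    gbm_space=GBMSearchSpace(ntree=(100, 100, 100), learn_rate=(0.1, 0.2, 0.1),
                             max_depth=(5, 5, 5), min_leaf=(20, 40, 20),
                             max_models=2),
    n_folds=5,
)
print(result.summary()[["scheme", "method", "model", "r2_mean", "slope_mean"]]
      .round(3).to_string(index=False))
```

Output:

```
analysis cows: 295, SNPs after QC: 195
h2 = 0.454 +/- 0.069, h_batch = 0.453 +/- 0.110
  scheme method model  r2_mean  slope_mean
herd_out bayesb    M1    0.499       0.889
herd_out bayesb    M4    0.649       1.030
herd_out    gbm    M1    0.406       1.324
herd_out    gbm    M4    0.435       1.094
 tenfold bayesb    M1    0.766       1.001
 tenfold bayesb    M4    0.793       0.997
 tenfold    gbm    M1    0.737       0.956
 tenfold    gbm    M4    0.769       0.994
```

The cohort was simulated with a glucose-like trait (*h*² target 0.36, batch
incidence target 0.44).  The Gibbs posterior recovers both ratios within
their posterior uncertainty; five cows were dropped by spectra/genotype QC.
In the prediction factorial, adding on-farm and genomic blocks to the
spectra-only baseline (M4 vs M1) raises out-of-sample R² in every cell, the
gain is largest when an unseen herd must be predicted, and random folds are
easier than herd-out extrapolation — calibration slopes near 1 indicate
unbiased predictions.

A command-line interface mirrors the library
(`ftirpred simulate | spectra-qc | kinship | ssgblup | bayesb | gbm |
run-experiment`), driven by a single YAML config for full runs.

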