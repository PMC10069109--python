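"""Cross-validation designs, evaluation statistics, and the experiment driver.

Three validation designs are provided:

* tenfold — balanced random partition into non-overlapping folds; each cow
  is validated exactly once;
* batch-out — whole herd/date batches held out, chosen by the Euclidean
  distance between batch-level genomic-relationship profiles so training and
  validation sets are as genetically separated as possible, with every batch
  validated at least once across replicates;
* herd-out — the two herd-direction splits (train herd 1 / validate herd 2,
  and the reverse).

Predictive ability R2 is the squared Pearson correlation between observed
and predicted phenotypes; RMSE and the calibration slope (OLS of observed on
predicted; 1 = unbiased) complete the per-replicate statistics.  Relative
difference RD = (r_m - r_M1) / r_M1 * 100 measures the percent gain of a
model over the spectra-only baseline M1.

``run_experiment`` runs the full factorial (method x model x scheme x trait)
with train/validation indices fixed across methods and models within a
scheme, mirroring how such comparisons are designed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import ConfigError, DataError
from .bayesb import BayesBRegressor
from .boosting import GBMSearchSpace, TunedGBMRegressor

__all__ = [
    "CVScheme",
    "AnalysisData",
    "ExperimentResult",
    "assign_tenfold",
    "assign_batch_out",
    "assign_herd_out",
    "r_squared",
    "rmse",
    "calibration_slope",
    "relative_difference",
    "rd_vs_h2_regression",
    "wavelength_trait_correlations",
    "model_blocks",
    "run_experiment",
]

MODEL_BLOCKS = {
    "M1": {"ftir"},
    "M2": {"ftir", "onfarm"},
    "M3": {"ftir", "snp"},
    "M4": {"ftir", "onfarm", "snp"},
}


@dataclass
class CVScheme:
    """A named list of (train_idx, valid_idx) replicates."""

    name: str
    splits: list[tuple[np.ndarray, np.ndarray]]
    seed: int = 0

    @property
    def n_replicates(self) -> int:
        return len(self.splits)


def assign_tenfold(n: int, seed: int = 0, n_folds: int = 10) -> CVScheme:
    """Balanced random partition; each fold validated once."""
    if n < n_folds:
        raise ConfigError(f"need at least {n_folds} cows, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    all_idx = np.arange(n)
    splits = [
        (np.setdiff1d(all_idx, f), np.sort(f)) for f in folds
    ]
    return CVScheme("tenfold", splits, seed)


def assign_batch_out(
    batch_labels: np.ndarray,
    G: np.ndarray,
    n_valid_batches: int = 3,
    n_replicates: int = 5,
    seed: int = 0,
) -> CVScheme:
    """Whole-batch hold-out driven by genomic distance between batches.

    Each batch's profile is the mean of its cows' rows of G; batches are
    ranked by mean Euclidean distance to the other batch profiles and
    chunked, farthest first, into validation groups of ``n_valid_batches``.
    If ``n_valid_batches * n_replicates`` cannot cover all batches the
    replicate count is raised so every batch is validated at least once.
    """
    batch_labels = np.asarray(batch_labels)
    levels = np.unique(batch_labels)
    B = levels.size
    if B < n_valid_batches + 1:
        raise ConfigError("need more batches than validation batches")
    profiles = np.stack(
        [G[batch_labels == b].mean(axis=0) for b in levels]
    )
    if np.isnan(profiles).any():
        raise DataError("batch with no genotyped cows: profile undefined")
    d = np.sqrt(
        ((profiles[:, None, :] - profiles[None, :, :]) ** 2).sum(axis=2)
    )
    farness = d.sum(axis=1) / max(B - 1, 1)
    rng = np.random.default_rng(seed)
    jitter = rng.permutation(B) * 1e-12  # deterministic seed-driven tie-break
    order = np.argsort(-(farness + jitter), kind="stable")

    n_replicates = max(n_replicates, int(np.ceil(B / n_valid_batches)))
    groups = [
        order[i : i + n_valid_batches]
        for i in range(0, B, n_valid_batches)
    ]
    # pad a short trailing group with the farthest batches not already in it
    if len(groups[-1]) < n_valid_batches:
        pad = [b for b in order if b not in groups[-1]]
        groups[-1] = np.r_[groups[-1],
                           pad[: n_valid_batches - len(groups[-1])]]
    while len(groups) < n_replicates:
        groups.append(order[:n_valid_batches])
    groups = groups[:max(n_replicates, len(groups))]

    all_idx = np.arange(batch_labels.size)
    splits = []
    for g in groups:
        valid_batches = set(levels[list(g)])
        vmask = np.isin(batch_labels, list(valid_batches))
        splits.append((all_idx[~vmask], all_idx[vmask]))
    return CVScheme("batch_out", splits, seed)


def assign_herd_out(herd_labels: np.ndarray) -> CVScheme:
    """Both herd directions as two replicates."""
    herd_labels = np.asarray(herd_labels)
    levels = np.unique(herd_labels)
    if levels.size != 2:
        raise ConfigError(f"herd-out CV requires exactly 2 herds, got {levels.size}")
    all_idx = np.arange(herd_labels.size)
    m2 = herd_labels == levels[1]
    return CVScheme(
        "herd_out",
        [(all_idx[~m2], all_idx[m2]), (all_idx[m2], all_idx[~m2])],
    )


def r_squared(y_obs, y_pred) -> float:
    """Squared Pearson correlation between observed and predicted values."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape:
        raise DataError("length mismatch")
    if y_obs.size < 3:
        raise DataError("need at least 3 observations")
    if y_obs.std() == 0 or y_pred.std() == 0:
        raise DataError("zero-variance input: R2 undefined")
    return float(np.corrcoef(y_obs, y_pred)[0, 1] ** 2)


def rmse(y_obs, y_pred) -> float:
    """Root mean squared error sqrt(mean((y - yhat)^2))."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape:
        raise DataError("length mismatch")
    if y_obs.size == 0:
        raise DataError("empty input")
    return float(np.sqrt(np.mean((y_obs - y_pred) ** 2)))


def calibration_slope(y_obs, y_pred) -> float:
    """OLS slope of observed on predicted; 1 = unbiased, >1 deflated."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    vp = y_pred.var()
    if vp == 0:
        raise DataError("zero-variance predictions: slope undefined")
    return float(np.cov(y_pred, y_obs, ddof=0)[0, 1] / vp)


def relative_difference(r_m: float, r_m1: float) -> float:
    """Percent gain RD = (r_m - r_M1) / r_M1 * 100 over the baseline model."""
    if r_m1 <= 0:
        raise DataError("baseline predictive ability must be positive")
    return float((r_m - r_m1) / r_m1 * 100.0)


def rd_vs_h2_regression(
    rd_per_trait, h2_per_trait
) -> tuple[float, float, float]:
    """OLS of per-trait RD on heritability: (slope, intercept, fit R2)."""
    rd = np.asarray(rd_per_trait, dtype=float)
    h2 = np.asarray(h2_per_trait, dtype=float)
    if rd.size < 3:
        raise DataError("need at least 3 traits")
    slope, intercept = np.polyfit(h2, rd, deg=1)
    fitted = slope * h2 + intercept
    sst = np.sum((rd - rd.mean()) ** 2)
    r2 = 1.0 - np.sum((rd - fitted) ** 2) / sst if sst > 0 else 1.0
    return float(slope), float(intercept), float(r2)


def wavelength_trait_correlations(
    spectra_values: np.ndarray,
    traits: pd.DataFrame,
    wavelength_idx: np.ndarray | None = None,
    wavenumbers: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each (selected) wavelength with each trait."""
    S = np.asarray(spectra_values, dtype=float)
    if wavelength_idx is None:
        wavelength_idx = np.arange(S.shape[1])
    wavelength_idx = np.asarray(wavelength_idx, dtype=int)
    rows = {}
    for j in wavelength_idx:
        col = S[:, j]
        if col.std() == 0:
            warnings.warn(f"zero-variance wavelength column {j}; skipped")
            continue
        key = wavenumbers[j] if wavenumbers is not None else j
        rows[key] = {
            t: float(np.corrcoef(col, traits[t].to_numpy())[0, 1])
            for t in traits.columns
        }
    return pd.DataFrame(rows).T


@dataclass
class AnalysisData:
    """Aligned, QC'd per-cow data ready for the prediction factorial."""

    ids: np.ndarray
    spectra: np.ndarray  # cows x wavelengths, preprocessed
    dim_class: np.ndarray
    parity_class: np.ndarray
    batch: np.ndarray
    herd: np.ndarray
    traits: pd.DataFrame
    snp: np.ndarray | None = None
    G: np.ndarray | None = None
    wavenumbers: np.ndarray | None = None

    def onfarm_onehot(self) -> np.ndarray:
        """Drop-first one-hot coding of DIM and parity classes."""
        cols = []
        for c in range(2, int(self.dim_class.max()) + 1):
            cols.append((self.dim_class == c).astype(float))
        for c in range(2, int(self.parity_class.max()) + 1):
            cols.append((self.parity_class == c).astype(float))
        return np.column_stack(cols) if cols else np.empty((self.ids.size, 0))

    def onfarm_ordinal(self) -> np.ndarray:
        return np.column_stack(
            [self.dim_class.astype(float), self.parity_class.astype(float)]
        )


def model_blocks(
    data: AnalysisData, model: str, method: str
) -> tuple[np.ndarray, np.ndarray | None]:
    """Assemble (penalized/feature matrix, covariate block) for one model.

    For BayesB the on-farm classes are an unpenalized one-hot block; for GBM
    they enter as ordinal features.  SNPs join the penalized/feature matrix
    for M3/M4.
    """
    blocks = MODEL_BLOCKS[model]
    parts = [data.spectra]
    if "snp" in blocks:
        if data.snp is None:
            raise ConfigError(f"model {model} needs genotypes")
        parts.append(data.snp)
    if method == "bayesb":
        X = np.column_stack(parts)
        F = data.onfarm_onehot() if "onfarm" in blocks else None
        return X, F
    if "onfarm" in blocks:
        parts.insert(1, data.onfarm_ordinal())
    return np.column_stack(parts), None


@dataclass
class ExperimentResult:
    """Tidy per-replicate results plus summary helpers."""

    results: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        g = self.results.groupby(["scheme", "method", "model", "trait"])
        out = g.agg(
            r2_mean=("r2", "mean"),
            r2_sd=("r2", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
            rmse_mean=("rmse", "mean"),
            slope_mean=("slope", "mean"),
            n_replicates=("r2", "size"),
        ).reset_index()
        return out

    def rd_table(self) -> pd.DataFrame:
        """RD (%) of each model vs M1 on mean R2, per scheme/method/trait."""
        s = self.summary()
        base = s[s.model == "M1"].set_index(["scheme", "method", "trait"])[
            "r2_mean"
        ]
        rows = []
        for _, r in s[s.model != "M1"].iterrows():
            r1 = base.get((r.scheme, r.method, r.trait), np.nan)
            if not np.isnan(r1) and r1 > 0:
                rows.append(
                    {
                        "scheme": r.scheme,
                        "method": r.method,
                        "model": r.model,
                        "trait": r.trait,
                        "rd": relative_difference(r.r2_mean, r1),
                    }
                )
        return pd.DataFrame(rows)


def build_schemes(
    data: AnalysisData,
    schemes=("tenfold", "batch_out", "herd_out"),
    seed: int = 0,
    n_folds: int = 10,
    n_valid_batches: int = 3,
    n_batch_replicates: int = 5,
) -> dict[str, CVScheme]:
    out: dict[str, CVScheme] = {}
    n = data.ids.size
    for s in schemes:
        if s == "tenfold":
            out[s] = assign_tenfold(n, seed=seed, n_folds=n_folds)
        elif s == "batch_out":
            if data.G is None:
                raise ConfigError("batch-out CV needs a genomic matrix G")
            out[s] = assign_batch_out(
                data.batch, data.G, n_valid_batches, n_batch_replicates, seed
            )
        elif s == "herd_out":
            out[s] = assign_herd_out(data.herd)
        else:
            raise ConfigError(f"unknown CV scheme {s!r}")
    return out


def run_experiment(
    data: AnalysisData,
    methods=("bayesb", "gbm"),
    models=("M1", "M2", "M3", "M4"),
    schemes=("tenfold", "batch_out", "herd_out"),
    traits=None,
    seed: int = 0,
    bayesb_params: dict | None = None,
    gbm_space: GBMSearchSpace | None = None,
    n_folds: int = 10,
    n_valid_batches: int = 3,
    n_batch_replicates: int = 5,
) -> ExperimentResult:
    """Full factorial prediction experiment.

    Train/validation indices are assigned once per scheme and reused for all
    methods and models.  Per cell, R2, RMSE and calibration slope are
    computed on the validation set of each replicate.
    """
    if traits is None:
        traits = list(data.traits.columns)
    scheme_objs = build_schemes(
        data, schemes, seed, n_folds, n_valid_batches, n_batch_replicates
    )
    bb = dict(n_iter=3000, burn_in=1000, thin=2)
    bb.update(bayesb_params or {})
    rows = []
    for trait in traits:
        y = data.traits[trait].to_numpy(dtype=float)
        for sname, scheme in scheme_objs.items():
            for model in models:
                for method in methods:
                    X, F = model_blocks(data, model, method)
                    for rep, (tr, va) in enumerate(scheme.splits):
                        if method == "bayesb":
                            est = BayesBRegressor(seed=seed + rep, **bb)
                            est.fit(
                                X[tr], y[tr],
                                X_fixed=None if F is None else F[tr],
                            )
                            pred = est.predict(
                                X[va], X_fixed=None if F is None else F[va]
                            )
                        else:
                            est = TunedGBMRegressor(
                                space=gbm_space, seed=seed + rep
                            )
                            est.fit(X[tr], y[tr])
                            pred = est.predict(X[va])
                        try:
                            r2 = r_squared(y[va], pred)
                        except DataError:
                            r2 = 0.0
                        try:
                            slope = calibration_slope(y[va], pred)
                        except DataError:
                            slope = np.nan
                        rows.append(
                            {
                                "scheme": sname,
                                "method": method,
                                "model": model,
                                "trait": trait,
                                "replicate": rep,
                                "n_valid": int(va.size),
                                "r2": r2,
                                "rmse": rmse(y[va], pred),
                                "slope": slope,
                            }
                        )
    return ExperimentResult(pd.DataFrame(rows))
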