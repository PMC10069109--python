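"""Milk FTIR spectra preprocessing.

The preprocessing pipeline mirrors standard milk mid-infrared chemometrics:
transmittance spectra are converted to absorbance (log10 of the reciprocal),
each wavelength channel is standardized to mean 0 / SD 1, replicate spectra of
the same sample are averaged, and outlier animals are removed by a
PCA/Mahalanobis screen at a chosen significance level.  Water-absorption
regions are deliberately retained: the downstream learners (BayesB, boosting)
are expected to cope with noisy channels, so no band excision or
scatter-correction is applied.

The pipeline order is fixed: absorbance -> standardize -> average replicates
-> outlier QC.  Columns are never dropped; rows only drop at the QC step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.decomposition import PCA

from ._exceptions import ConfigError, DegenerateChannelError, DomainError, MappingError

__all__ = [
    "SpectraMatrix",
    "ColumnStandardizer",
    "PCAMahalanobisDetector",
    "transmittance_to_absorbance",
    "standardize_columns",
    "average_replicates",
    "mahalanobis_outlier_qc",
    "preprocess_pipeline",
]


@dataclass
class SpectraMatrix:
    """Per-sample FTIR spectra with a wavenumber axis.

    Rows are sample (replicate) spectra, columns are wavelength channels on a
    strictly monotone wavenumber axis in cm^-1 (conventionally descending,
    e.g. 5011 -> 925).  ``ids`` identifies the animal each row belongs to;
    ``replicate`` optionally tags replicate measurements of the same animal.
    """

    values: np.ndarray
    wavenumbers: np.ndarray
    ids: np.ndarray
    replicate: np.ndarray | None = None
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.ids = np.asarray(self.ids)
        if self.values.ndim != 2:
            raise ConfigError("spectra values must be a 2-D matrix")
        if self.wavenumbers.shape[0] != self.values.shape[1]:
            raise ConfigError(
                f"wavenumber axis length {self.wavenumbers.shape[0]} does not "
                f"match {self.values.shape[1]} spectral columns"
            )
        d = np.diff(self.wavenumbers)
        if self.wavenumbers.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ConfigError("wavenumber axis must be strictly monotone")
        if self.ids.shape[0] != self.values.shape[0]:
            raise ConfigError("one id per spectra row is required")
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate)
            if self.replicate.shape[0] != self.values.shape[0]:
                raise MappingError("replicate tags do not match spectra rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.values.shape[1]


class ColumnStandardizer(BaseEstimator):
    """Standardize columns to mean 0, SD 1 using the sample SD (n-1).

    A thin transformer; unlike :class:`sklearn.preprocessing.StandardScaler`
    it uses the n-1 denominator, matching the regression conventions used
    downstream, and refuses zero-variance columns.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if np.any(self.scale_ == 0):
            raise DegenerateChannelError(np.flatnonzero(self.scale_ == 0))
        return (X - self.mean_) / self.scale_

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


class PCAMahalanobisDetector(BaseEstimator, OutlierMixin):
    """Outlier screen: PCA scores + Mahalanobis distance vs a chi-square cut.

    Components are retained up to the smallest number explaining at least
    ``explained_variance`` of the total (capped at min(n-1, p)); the squared
    Mahalanobis distance of each sample in that score space is compared with
    the chi-square(k) quantile at 1 - alpha.
    """

    def __init__(self, alpha: float = 0.05, explained_variance: float = 0.95):
        self.alpha = alpha
        self.explained_variance = explained_variance

    def fit(self, X, y=None):
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        k_max = min(n - 1, p)
        pca = PCA(n_components=k_max, svd_solver="full").fit(X)
        ratio = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(ratio, self.explained_variance) + 1)
        k = min(k, k_max)
        self.n_components_ = k
        self.pca_ = pca
        self.threshold_ = stats.chi2.ppf(1.0 - self.alpha, df=k)
        return self

    def score_samples(self, X):
        """Squared Mahalanobis distance in the retained component space."""
        scores = self.pca_.transform(np.asarray(X, dtype=float))
        k = self.n_components_
        return np.sum(scores[:, :k] ** 2 / self.pca_.explained_variance_[:k], axis=1)

    def predict(self, X):
        """+1 for inliers, -1 for outliers (sklearn convention)."""
        return np.where(self.score_samples(X) > self.threshold_, -1, 1)


def transmittance_to_absorbance(spectra: SpectraMatrix) -> SpectraMatrix:
    """Convert transmittance T in (0, 1] to absorbance A = log10(1/T)."""
    bad = ~(spectra.values > 0)
    if np.any(bad):
        r, c = np.argwhere(bad)[0]
        raise DomainError(
            "non-positive transmittance at row id "
            f"{spectra.ids[r]!r}, wavenumber {spectra.wavenumbers[c]:g} cm^-1 "
            f"(value {spectra.values[r, c]:g})"
        )
    return replace(spectra, values=np.log10(1.0 / spectra.values), standardized=False)


def standardize_columns(spectra: SpectraMatrix) -> SpectraMatrix:
    """Center and scale each wavelength channel to mean 0, SD 1 (sample SD)."""
    sd = spectra.values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DegenerateChannelError(spectra.wavenumbers[sd == 0])
    out = ColumnStandardizer().fit_transform(spectra.values)
    return replace(spectra, values=out, standardized=True)


def average_replicates(spectra: SpectraMatrix) -> SpectraMatrix:
    """Average replicate rows per animal, preserving first-appearance order."""
    ids = spectra.ids
    uniq, first = np.unique(ids, return_index=True)
    uniq = uniq[np.argsort(first)]  # keep input order
    rows = np.empty((uniq.size, spectra.n_wavelengths))
    for i, u in enumerate(uniq):
        rows[i] = spectra.values[ids == u].mean(axis=0)
    return SpectraMatrix(
        values=rows,
        wavenumbers=spectra.wavenumbers,
        ids=uniq,
        replicate=None,
        standardized=spectra.standardized,
    )


def mahalanobis_outlier_qc(
    spectra: SpectraMatrix,
    alpha: float = 0.05,
    explained_variance: float = 0.95,
) -> tuple[SpectraMatrix, np.ndarray]:
    """Remove animals flagged by the PCA/Mahalanobis screen.

    Returns the filtered matrix and the removed animal ids.
    """
    det = PCAMahalanobisDetector(alpha=alpha, explained_variance=explained_variance)
    det.fit(spectra.values)
    keep = det.predict(spectra.values) == 1
    removed = spectra.ids[~keep]
    filtered = SpectraMatrix(
        values=spectra.values[keep],
        wavenumbers=spectra.wavenumbers,
        ids=spectra.ids[keep],
        replicate=None if spectra.replicate is None else spectra.replicate[keep],
        standardized=spectra.standardized,
    )
    return filtered, removed


def preprocess_pipeline(
    spectra: SpectraMatrix,
    alpha: float = 0.05,
    from_transmittance: bool = True,
) -> tuple[SpectraMatrix, np.ndarray]:
    """Full preprocessing chain: absorbance -> standardize -> average -> QC."""
    if from_transmittance:
        spectra = transmittance_to_absorbance(spectra)
    spectra = standardize_columns(spectra)
    spectra = average_replicates(spectra)
    return mahalanobis_outlier_qc(spectra, alpha=alpha)
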