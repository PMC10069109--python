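"""Bayesian animal model (ssGBLUP) for variance components via Gibbs sampling.

Model per trait::

    y = X b + W h + Z a + e,
    a ~ N(0, H sigma2_a),  h ~ N(0, I sigma2_batch),  e ~ N(0, I sigma2_e)

where X holds the fixed DIM/parity class effects, W the herd/date batch
factor, and H the combined pedigree+genomic relationship matrix (the sampler
consumes H^-1 directly).  Fixed effects get flat priors; the three variances
get scaled-inverse-chi-square priors (the univariate inverse Wishart).
Location effects are updated single-site with residual updating; variances
from their conjugate full conditionals.

Summaries follow the conventions of the variance-component literature:
heritability h2 = sigma2_a / (sigma2_a + sigma2_e)  (batch variance excluded
from the denominator by definition here), and batch incidence
h_batch = sigma2_batch / (sigma2_a + sigma2_batch + sigma2_e), both computed
per stored sample and summarized as the posterior mean of the ratios.
Convergence is monitored with the Geweke diagnostic (first 10% vs last 50%
of the stored chain, spectral-density variance estimate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats
from sklearn.base import BaseEstimator

from ._exceptions import ConfigError, DataError
from .kinship import KinshipBundle

__all__ = [
    "ChainConfig",
    "PosteriorSummary",
    "GibbsAnimalModel",
    "gibbs_animal_model",
    "heritability",
    "batch_incidence",
    "geweke_diagnostic",
    "onfarm_design",
]


@dataclass
class ChainConfig:
    """MCMC chain settings (defaults: 500k cycles, 100k burn-in, thin 5)."""

    n_iter: int = 500_000
    burn_in: int = 100_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iter:
            raise ConfigError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ConfigError("thin must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


#: Desk-scale default used by the high-level fitters; the full-scale chain
#: is available by passing ChainConfig() explicitly.
DESK_CHAIN = ChainConfig(n_iter=50_000, burn_in=10_000, thin=5)


@dataclass
class PosteriorSummary:
    """Posterior summaries of one Gibbs run."""

    var_samples: np.ndarray  # (n_stored, 3): sigma2_a, sigma2_batch, sigma2_e
    var_mean: np.ndarray
    var_sd: np.ndarray
    h2_mean: float
    h2_sd: float
    hbatch_mean: float
    hbatch_sd: float
    n_stored: int
    geweke_p: dict[str, float]
    converged: bool
    fixed_mean: np.ndarray
    batch_mean: np.ndarray
    animal_mean: np.ndarray


def heritability(sigma2_a, sigma2_e):
    """h2 = sigma2_a / (sigma2_a + sigma2_e), elementwise over samples."""
    sigma2_a = np.asarray(sigma2_a, dtype=float)
    sigma2_e = np.asarray(sigma2_e, dtype=float)
    tot = sigma2_a + sigma2_e
    if np.any(tot == 0):
        raise DataError("sigma2_a + sigma2_e is zero: heritability undefined")
    if np.any(sigma2_a < 0) or np.any(sigma2_e < 0):
        raise DataError("variances must be non-negative")
    out = sigma2_a / tot
    return float(out) if out.ndim == 0 else out


def batch_incidence(sigma2_a, sigma2_batch, sigma2_e):
    """h_batch = sigma2_batch / (sigma2_a + sigma2_batch + sigma2_e)."""
    sigma2_a = np.asarray(sigma2_a, dtype=float)
    sigma2_batch = np.asarray(sigma2_batch, dtype=float)
    sigma2_e = np.asarray(sigma2_e, dtype=float)
    tot = sigma2_a + sigma2_batch + sigma2_e
    if np.any(tot == 0):
        raise DataError("total variance is zero: batch incidence undefined")
    if np.any(sigma2_a < 0) or np.any(sigma2_batch < 0) or np.any(sigma2_e < 0):
        raise DataError("variances must be non-negative")
    out = sigma2_batch / tot
    return float(out) if out.ndim == 0 else out


def _spectral_density_zero(x: np.ndarray) -> float:
    """Spectral density at frequency zero via a Bartlett-windowed HAC sum."""
    n = x.size
    xc = x - x.mean()
    lag_max = max(1, int(np.floor(n ** (1.0 / 3.0))))
    gamma0 = float(xc @ xc) / n
    s = gamma0
    for k in range(1, lag_max + 1):
        gk = float(xc[k:] @ xc[:-k]) / n
        s += 2.0 * (1.0 - k / (lag_max + 1.0)) * gk
    return max(s, 1e-300)


def geweke_diagnostic(
    samples: np.ndarray, first: float = 0.1, last: float = 0.5
) -> tuple[float, float]:
    """Geweke convergence z-score and two-sided p-value.

    Compares the mean of the first ``first`` fraction of the chain with the
    mean of the last ``last`` fraction, using spectral-density estimates of
    the variance of each segment mean.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 100:
        raise DataError(f"need at least 100 stored samples, got {x.size}")
    if np.ptp(x) == 0:
        raise DataError("constant chain: Geweke diagnostic undefined")
    n1 = int(np.floor(first * x.size))
    n2 = int(np.floor(last * x.size))
    a, b = x[:n1], x[-n2:]
    var = _spectral_density_zero(a) / n1 + _spectral_density_zero(b) / n2
    z = (a.mean() - b.mean()) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


@njit(cache=False)
def _gibbs_core(
    y,
    X,
    batch_rows,
    batch_off,
    anim_rows,
    anim_off,
    Hinv,
    n_iter,
    burn_in,
    thin,
    prior_df,
    Sa,
    Sb,
    Se,
    sig_a0,
    sig_b0,
    sig_e0,
    update_vars,
    seed,
):  # pragma: no cover - exercised through the Python wrapper
    np.random.seed(seed)
    n = y.shape[0]
    pf = X.shape[1]
    nb = batch_off.shape[0] - 1
    q = Hinv.shape[0]

    xtx = np.empty(pf)
    for j in range(pf):
        s = 0.0
        for r in range(n):
            s += X[r, j] * X[r, j]
        xtx[j] = s

    b = np.zeros(pf)
    h = np.zeros(nb)
    a = np.zeros(q)
    sig_a, sig_b, sig_e = sig_a0, sig_b0, sig_e0

    e = y.copy()

    n_stored = (n_iter - burn_in) // thin
    out = np.zeros((n_stored, 3))
    b_sum = np.zeros(pf)
    h_sum = np.zeros(nb)
    a_sum = np.zeros(q)
    stored = 0

    for it in range(n_iter):
        # fixed effects, flat prior
        for j in range(pf):
            old = b[j]
            rhs = 0.0
            for r in range(n):
                rhs += X[r, j] * (e[r] + X[r, j] * old)
            mean = rhs / xtx[j]
            new = mean + np.random.standard_normal() * np.sqrt(sig_e / xtx[j])
            diff = new - old
            for r in range(n):
                e[r] -= X[r, j] * diff
            b[j] = new

        # batch effects
        for k in range(nb):
            lo, hi = batch_off[k], batch_off[k + 1]
            cnt = hi - lo
            old = h[k]
            rhs = 0.0
            for t in range(lo, hi):
                rhs += e[batch_rows[t]] + old
            lhs = cnt + sig_e / sig_b
            mean = rhs / lhs
            new = mean + np.random.standard_normal() * np.sqrt(sig_e / lhs)
            diff = new - old
            for t in range(lo, hi):
                e[batch_rows[t]] -= diff
            h[k] = new

        # animal effects (all q animals, phenotyped or not)
        lam = sig_e / sig_a
        for i in range(q):
            lo, hi = anim_off[i], anim_off[i + 1]
            cnt = hi - lo
            old = a[i]
            rhs = 0.0
            for t in range(lo, hi):
                rhs += e[anim_rows[t]] + old
            hdot = 0.0
            for jj in range(q):
                hdot += Hinv[i, jj] * a[jj]
            hdot -= Hinv[i, i] * old
            rhs -= lam * hdot
            lhs = cnt + lam * Hinv[i, i]
            mean = rhs / lhs
            new = mean + np.random.standard_normal() * np.sqrt(sig_e / lhs)
            diff = new - old
            for t in range(lo, hi):
                e[anim_rows[t]] -= diff
            a[i] = new

        if update_vars:
            # sigma2_a | a  ~  scaled-inv-chi2(q + df, (a'Hinv a + df Sa)/(q+df))
            quad = 0.0
            for i in range(q):
                s = 0.0
                for jj in range(q):
                    s += Hinv[i, jj] * a[jj]
                quad += a[i] * s
            sig_a = (quad + prior_df * Sa) / np.random.chisquare(q + prior_df)
            if nb > 0:
                hh = 0.0
                for k in range(nb):
                    hh += h[k] * h[k]
                sig_b = (hh + prior_df * Sb) / np.random.chisquare(nb + prior_df)
            ee = 0.0
            for r in range(n):
                ee += e[r] * e[r]
            sig_e = (ee + prior_df * Se) / np.random.chisquare(n + prior_df)

        if it >= burn_in and (it - burn_in) % thin == 0:
            out[stored, 0] = sig_a
            out[stored, 1] = sig_b
            out[stored, 2] = sig_e
            for j in range(pf):
                b_sum[j] += b[j]
            for k in range(nb):
                h_sum[k] += h[k]
            for i in range(q):
                a_sum[i] += a[i]
            stored += 1

    return out, b_sum / stored, h_sum / stored, a_sum / stored


def _rows_by_group(codes: np.ndarray, n_groups: int) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(codes, kind="stable")
    off = np.zeros(n_groups + 1, dtype=np.int64)
    counts = np.bincount(codes, minlength=n_groups)
    off[1:] = np.cumsum(counts)
    return order.astype(np.int64), off


class GibbsAnimalModel(BaseEstimator):
    """Gibbs sampler for the single-trait animal model with a batch effect.

    Parameters follow weakly-informative defaults: scaled-inverse-chi-square
    priors with ``prior_df`` degrees of freedom and scales set from the
    phenotypic variance split as 1/2 residual, 1/4 genetic, 1/4 batch.
    Setting ``update_variances=False`` holds the variances at
    ``start_variances`` and samples only location effects (useful for
    closed-form cross-checks).
    """

    def __init__(
        self,
        chain: ChainConfig | None = None,
        prior_df: float = 4.0,
        update_variances: bool = True,
        start_variances: tuple[float, float, float] | None = None,
    ):
        self.chain = chain
        self.prior_df = prior_df
        self.update_variances = update_variances
        self.start_variances = start_variances

    def fit(self, y, X, batch_codes, animal_codes, Hinv):
        """Run the chain.

        ``batch_codes`` are 0-based batch indices per record (or None),
        ``animal_codes`` 0-based indices into the H^-1 ordering.
        """
        chain = self.chain if self.chain is not None else DESK_CHAIN
        y = np.ascontiguousarray(y, dtype=float)
        X = np.ascontiguousarray(X, dtype=float)
        Hinv = np.ascontiguousarray(Hinv, dtype=float)
        n = y.size
        if X.shape[0] != n:
            raise DataError("X rows must match y")
        vy = y.var(ddof=1)
        if vy == 0:
            raise DataError("constant phenotype")
        Sa = Sb = 0.25 * vy
        Se = 0.5 * vy
        if self.start_variances is not None:
            sig_a0, sig_b0, sig_e0 = self.start_variances
        else:
            sig_a0, sig_b0, sig_e0 = 0.25 * vy, 0.25 * vy, 0.5 * vy

        if batch_codes is None:
            batch_rows = np.empty(0, dtype=np.int64)
            batch_off = np.zeros(1, dtype=np.int64)
        else:
            batch_codes = np.asarray(batch_codes, dtype=np.int64)
            nb = int(batch_codes.max()) + 1
            batch_rows, batch_off = _rows_by_group(batch_codes, nb)
        animal_codes = np.asarray(animal_codes, dtype=np.int64)
        anim_rows, anim_off = _rows_by_group(animal_codes, Hinv.shape[0])

        out, b_mean, h_mean, a_mean = _gibbs_core(
            y,
            X,
            batch_rows,
            batch_off,
            anim_rows,
            anim_off,
            Hinv,
            chain.n_iter,
            chain.burn_in,
            chain.thin,
            float(self.prior_df),
            Sa,
            Sb,
            Se,
            float(sig_a0),
            float(sig_b0),
            float(sig_e0),
            self.update_variances,
            chain.seed % (2**31),
        )

        h2 = heritability(out[:, 0], out[:, 2])
        hb = batch_incidence(out[:, 0], out[:, 1], out[:, 2])
        geweke = {}
        if self.update_variances and out.shape[0] >= 100:
            for name, col in zip(("sigma2_a", "sigma2_batch", "sigma2_e"), out.T):
                try:
                    geweke[name] = geweke_diagnostic(col)[1]
                except DataError:
                    geweke[name] = np.nan
        converged = bool(geweke.get("sigma2_a", 1.0) > 0.05)

        self.summary_ = PosteriorSummary(
            var_samples=out,
            var_mean=out.mean(axis=0),
            var_sd=out.std(axis=0, ddof=1),
            h2_mean=float(np.mean(h2)),
            h2_sd=float(np.std(h2, ddof=1)),
            hbatch_mean=float(np.mean(hb)),
            hbatch_sd=float(np.std(hb, ddof=1)),
            n_stored=out.shape[0],
            geweke_p=geweke,
            converged=converged,
            fixed_mean=b_mean,
            batch_mean=h_mean,
            animal_mean=a_mean,
        )
        return self


def onfarm_design(
    dim_class: np.ndarray,
    parity_class: np.ndarray,
    n_dim_classes: int = 6,
    n_parity_classes: int = 4,
) -> np.ndarray:
    """Fixed-effect design: intercept + DIM and parity class dummies.

    Treatment (reference) coding: the first class of each factor is absorbed
    into the intercept, so the design has full column rank under flat priors.
    """
    dim_class = np.asarray(dim_class, dtype=int)
    parity_class = np.asarray(parity_class, dtype=int)
    n = dim_class.size
    cols = [np.ones(n)]
    for c in range(2, n_dim_classes + 1):
        cols.append((dim_class == c).astype(float))
    for c in range(2, n_parity_classes + 1):
        cols.append((parity_class == c).astype(float))
    return np.column_stack(cols)


def gibbs_animal_model(
    cow_table: pd.DataFrame,
    kinship: KinshipBundle,
    trait: str,
    chain: ChainConfig | None = None,
    prior_df: float = 4.0,
) -> PosteriorSummary:
    """Fit the animal model for one trait from a cow table and kinship bundle.

    The cow table must carry ``animal``, ``batch``, ``dim_class`` and
    ``parity_class`` columns plus the trait column; animals are matched to
    the kinship ``id_order`` (which may include non-phenotyped ancestors).
    """
    sub = cow_table.dropna(subset=[trait])
    y = sub[trait].to_numpy(dtype=float)
    X = onfarm_design(
        sub["dim_class"].to_numpy(),
        sub["parity_class"].to_numpy(),
        int(cow_table["dim_class"].max()),
        int(cow_table["parity_class"].max()),
    )
    batches = pd.Categorical(sub["batch"]).codes.astype(np.int64)
    pos = {a: i for i, a in enumerate(kinship.id_order)}
    try:
        animal_codes = np.array([pos[a] for a in sub["animal"]], dtype=np.int64)
    except KeyError as err:
        raise DataError(f"animal {err} missing from kinship id_order") from err
    model = GibbsAnimalModel(chain=chain, prior_df=prior_df)
    model.fit(y, X, batches, animal_codes, kinship.Hinv)
    return model.summary_
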