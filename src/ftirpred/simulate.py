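"""Synthetic dairy-cow populations with linked spectra, genotypes and traits.

The generator emulates the statistical structure of a two-herd Holstein
cohort sampled in herd/date batches: a three-generation pedigree, SNP
genotypes gene-dropped through it, blood-metabolite phenotypes built from
additive-genetic, batch, fixed DIM/parity and residual layers, and milk FTIR
spectra that carry a tunable share of the non-systematic metabolite signal
through band-shaped loadings.

Phenotype model per trait::

    y = mu + dim_effect[class] + parity_effect[class] + a + b_batch + e

with components rescaled so the realized variance ratios hit the configured
targets exactly: h2 = var(a)/(var(a)+var(e)) and
h_batch = var(b)/(var(a)+var(b)+var(e)).

Spectra per cow (two replicate rows) are a smooth baseline, a herd-level
offset, a batch-level drift curve (instrument/date structure that makes
batch-out and herd-out prediction genuinely harder than random folds),
trait-loading bands times the spectra-visible latent signal, and channel
noise, emitted either as raw transmittance in (0, 1) or as absorbance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import ConfigError
from .kinship import GenotypeSet, Pedigree
from .spectra import SpectraMatrix

__all__ = [
    "TraitTargets",
    "SimConfig",
    "SimTruth",
    "SimBundle",
    "DEFAULT_TRAITS",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_phenotypes_and_spectra",
    "simulate_dataset",
]


@dataclass(frozen=True)
class TraitTargets:
    """Variance-ratio targets for one simulated metabolite."""

    h2: float
    hbatch: float
    mean: float = 0.0


#: Default metabolite panel: heritability and batch-incidence targets spanning
#: the range typical of blood metabolic indicators in dairy cows (h2 from
#: ~0.05 to ~0.60, batch incidence from ~0.01 to ~0.44).
DEFAULT_TRAITS: dict[str, TraitTargets] = {
    "glucose": TraitTargets(0.360, 0.444),
    "bhba": TraitTargets(0.125, 0.158),
    "urea": TraitTargets(0.180, 0.361),
    "ast": TraitTargets(0.360, 0.110),
    "ggt": TraitTargets(0.427, 0.013),
    "pon": TraitTargets(0.604, 0.076),
    "romt": TraitTargets(0.130, 0.083),
    "aopp": TraitTargets(0.089, 0.245),
    "frap": TraitTargets(0.050, 0.244),
    "ceruloplasmin": TraitTargets(0.374, 0.072),
    "prott": TraitTargets(0.090, 0.066),
    "globulins": TraitTargets(0.091, 0.065),
    "calcium": TraitTargets(0.125, 0.200),
    "potassium": TraitTargets(0.248, 0.286),
    "zinc": TraitTargets(0.346, 0.413),
}


@dataclass
class SimConfig:
    """Configuration of the synthetic population.

    ``spectral_signal`` is the share of each trait's non-systematic variance
    (genetic + batch + residual) that is recoverable from the spectra in the
    infinite-data limit.
    """

    n_cows: int = 1020
    n_snps: int = 2000
    n_wavelengths: int = 1060
    n_batches: int = 16
    herd_sizes: tuple[int, int] = (945, 75)
    n_dim_classes: int = 6
    n_parity_classes: int = 4
    n_generations: int = 3
    traits: dict[str, TraitTargets] = field(
        default_factory=lambda: dict(DEFAULT_TRAITS)
    )
    spectral_signal: float = 0.7
    prop_qtl: float = 0.05
    maf_range: tuple[float, float] = (0.05, 0.5)
    fixed_effect_scale: float = 0.3
    herd_spectral_offset: float = 0.6
    batch_spectral_offset: float = 0.35
    channel_noise_sd: float = 0.05
    replicate_noise_sd: float = 0.02
    outlier_fraction: float = 0.0
    outlier_offset: float = 12.0
    missing_rate: float = 0.0
    emit: str = "transmittance"  # or "absorbance"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cows < 4:
            raise ConfigError("n_cows must be at least 4")
        if sum(self.herd_sizes) != self.n_cows:
            raise ConfigError(
                f"herd sizes {self.herd_sizes} must sum to n_cows={self.n_cows}"
            )
        if not 0.0 <= self.spectral_signal <= 1.0:
            raise ConfigError("spectral_signal must be in [0, 1]")
        for name, t in self.traits.items():
            if not (0.0 <= t.h2 < 1.0 and 0.0 <= t.hbatch < 1.0):
                raise ConfigError(f"trait {name}: ratios must lie in [0, 1)")
            if t.h2 + t.hbatch >= 1.0:
                raise ConfigError(
                    f"trait {name}: h2 + hbatch must be < 1, got "
                    f"{t.h2} + {t.hbatch}"
                )
        if self.emit not in ("transmittance", "absorbance"):
            raise ConfigError("emit must be 'transmittance' or 'absorbance'")


@dataclass
class SimTruth:
    """Simulation-side ground truth for downstream checks."""

    snp_effects: dict[str, np.ndarray]
    breeding_values: dict[str, np.ndarray]
    batch_effects: dict[str, np.ndarray]
    dim_effects: dict[str, np.ndarray]
    parity_effects: dict[str, np.ndarray]
    realized_h2: dict[str, float]
    realized_hbatch: dict[str, float]
    loading_masks: dict[str, np.ndarray]
    latent: dict[str, np.ndarray]
    allele_freqs: np.ndarray
    outlier_ids: np.ndarray


@dataclass
class SimBundle:
    """Everything one simulated study produces."""

    config: SimConfig
    pedigree: Pedigree
    genotypes: GenotypeSet
    cow_table: pd.DataFrame
    spectra: SpectraMatrix
    truth: SimTruth

    @property
    def study_ids(self) -> np.ndarray:
        return self.cow_table["animal"].to_numpy()


def _scale_to_var(x: np.ndarray, target: float) -> np.ndarray:
    if target <= 0:
        return np.zeros_like(x)
    v = x.var(ddof=1)
    if v == 0:
        raise ConfigError("cannot scale a constant component to positive variance")
    return x * np.sqrt(target / v)


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Three-generation pedigree whose last ``n_cows`` records are the cows.

    Founders have unknown (0) parents; every non-founder's sire and dam
    appear earlier in the ordering.  ``n_generations=1`` gives a founder-only
    pedigree.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_cows
    if config.n_generations <= 1:
        z = np.zeros(n, dtype=np.int64)
        return Pedigree(np.arange(1, n + 1), z, z)

    n_sires = max(2, n // 20)
    n_dams = max(2, n // 2)
    animal: list[int] = []
    sire: list[int] = []
    dam: list[int] = []
    next_id = 1

    def add(s: int, d: int) -> int:
        nonlocal next_id
        animal.append(next_id)
        sire.append(s)
        dam.append(d)
        next_id += 1
        return animal[-1]

    sires = [add(0, 0) for _ in range(n_sires)]
    dams = [add(0, 0) for _ in range(n_dams)]
    for _ in range(config.n_generations - 2):
        new_sires = [
            add(rng.choice(sires), rng.choice(dams)) for _ in range(n_sires)
        ]
        new_dams = [
            add(rng.choice(sires), rng.choice(dams)) for _ in range(n_dams)
        ]
        sires, dams = new_sires, new_dams
    for _ in range(n):
        add(rng.choice(sires), rng.choice(dams))
    return Pedigree(np.array(animal), np.array(sire), np.array(dam))


def simulate_genotypes(
    pedigree: Pedigree,
    config: SimConfig,
    allele_freqs: np.ndarray | None = None,
    study_only: bool = True,
) -> GenotypeSet:
    """Gene-drop SNP dosages through the pedigree.

    Founder genotypes are Binomial(2, p) draws with allele frequencies
    uniform on ``config.maf_range`` (or supplied explicitly); each offspring
    receives one allele per parent, transmitted with probability equal to
    half the parental dosage.  With ``study_only`` the returned set covers
    the last ``n_cows`` pedigree records (the phenotyped cohort).
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    m = config.n_snps
    if allele_freqs is None:
        lo, hi = config.maf_range
        allele_freqs = rng.uniform(lo, hi, size=m)
    p = np.asarray(allele_freqs, dtype=float)

    n_all = len(pedigree)
    pos = {a: i for i, a in enumerate(pedigree.animal)}
    D = np.empty((n_all, m), dtype=np.int8)
    for i in range(n_all):
        s, d = pedigree.sire[i], pedigree.dam[i]
        dose = np.zeros(m, dtype=np.int8)
        for parent in (s, d):
            if parent == 0:
                dose += (rng.random(m) < p).astype(np.int8)
            else:
                dose += (rng.random(m) < D[pos[parent]] / 2.0).astype(np.int8)
        D[i] = dose

    ids = pedigree.animal
    if study_only:
        ids = ids[-config.n_cows :]
        D = D[-config.n_cows :]
    D = D.astype(float)
    if config.missing_rate > 0:
        mask = rng.random(D.shape) < config.missing_rate
        D[mask] = np.nan
    meta = pd.DataFrame(
        {
            "snp": [f"snp{j:06d}" for j in range(m)],
            "chrom": (np.arange(m) % 29) + 1,
            "pos": (np.arange(m) // 29 + 1) * 1000,
            "a1": "A",
            "a2": "B",
        }
    )
    return GenotypeSet(D, meta, ids)


def _herd_batch_assignment(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    n1, n2 = config.herd_sizes
    herd = np.r_[np.ones(n1, dtype=int), np.full(n2, 2, dtype=int)]
    nb2 = min(max(1, round(config.n_batches * n2 / config.n_cows)) or 1,
              config.n_batches - 1)
    nb2 = max(1, nb2)
    nb1 = config.n_batches - nb2
    b1 = np.array_split(np.arange(n1), nb1)
    b2 = np.array_split(np.arange(n2), nb2)
    batch = np.empty(config.n_cows, dtype=int)
    k = 1
    for chunk in b1:
        batch[chunk] = k
        k += 1
    for chunk in b2:
        batch[n1 + chunk] = k
        k += 1
    return herd, batch


def _smooth_curve(rng: np.random.Generator, p: int, n_bumps: int) -> np.ndarray:
    """Random smooth curve: a few broad Gaussian bumps on the channel axis."""
    x = np.arange(p)
    curve = np.zeros(p)
    for _ in range(n_bumps):
        c = rng.uniform(0, p)
        w = rng.uniform(p / 20, p / 5)
        curve += rng.normal() * np.exp(-0.5 * ((x - c) / w) ** 2)
    return curve


def _trait_loadings(
    rng: np.random.Generator, p: int
) -> tuple[np.ndarray, np.ndarray]:
    """Band-shaped loadings: 10-30 contiguous Gaussian windows per trait."""
    x = np.arange(p)
    n_win = rng.integers(10, 31)
    load = np.zeros(p)
    mask = np.zeros(p, dtype=bool)
    for _ in range(n_win):
        c = rng.uniform(0, p)
        w = rng.uniform(max(2.0, p / 200), max(4.0, p / 60))
        amp = rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0])
        bump = np.exp(-0.5 * ((x - c) / w) ** 2)
        load += amp * bump
        mask |= np.abs(x - c) <= 2 * w
    return load, mask


def simulate_phenotypes_and_spectra(
    genotypes: GenotypeSet,
    config: SimConfig,
) -> tuple[pd.DataFrame, SpectraMatrix, SimTruth]:
    """Build the cow table, replicate spectra and ground truth.

    Phenotype components are rescaled so the realized (sample) variance
    ratios equal the targets exactly; the spectra carry the latent
    ``a + b + e`` part of each trait at signal share ``spectral_signal``.
    """
    rng = np.random.default_rng(config.rng_seed + 2)
    n = config.n_cows
    if genotypes.n_samples != n:
        raise ConfigError("genotype set must cover the study cows")
    p_wl = config.n_wavelengths

    herd, batch = _herd_batch_assignment(config)
    dim = np.clip(rng.normal(188, 106, size=n), 5, 400).round().astype(int)
    parity = rng.choice(
        np.arange(1, config.n_parity_classes + 1),
        size=n,
        p=_parity_probs(config.n_parity_classes),
    )
    dim_class = np.digitize(dim, [60, 121, 181, 241, 301]) + 1
    dim_class = np.clip(dim_class, 1, config.n_dim_classes)

    M = np.asarray(genotypes.dosages, dtype=float)
    Mc = M - M.mean(axis=0)

    cow = pd.DataFrame(
        {"animal": genotypes.sample_ids, "herd": herd, "batch": batch,
         "dim": dim, "parity": parity}
    )

    snp_effects: dict[str, np.ndarray] = {}
    breeding_values: dict[str, np.ndarray] = {}
    batch_effects: dict[str, np.ndarray] = {}
    dim_effects: dict[str, np.ndarray] = {}
    parity_effects: dict[str, np.ndarray] = {}
    realized_h2: dict[str, float] = {}
    realized_hb: dict[str, float] = {}
    masks: dict[str, np.ndarray] = {}
    latents: dict[str, np.ndarray] = {}

    x = np.arange(p_wl)
    baseline = 0.3 * np.sin(x / p_wl * 3.2) + _smooth_curve(rng, p_wl, 4) * 0.3
    herd_shape = _smooth_curve(rng, p_wl, 3)
    herd_shape *= config.herd_spectral_offset / max(herd_shape.std(), 1e-12)
    batch_shapes = np.stack(
        [_smooth_curve(rng, p_wl, 3) for _ in range(config.n_batches)]
    )
    sds = batch_shapes.std(axis=1, keepdims=True)
    batch_shapes *= config.batch_spectral_offset / np.maximum(sds, 1e-12)

    raw = np.tile(baseline, (n, 1))
    # cohort-level structure (herd offset, per-batch drift) is informative
    # about batch membership and hence about y's batch component; with
    # spectral_signal = 0 the spectra must carry no information about the
    # phenotypes at all, so it is only added when signal is present
    if config.spectral_signal > 0:
        raw += np.outer(herd == 2, herd_shape)
        raw += batch_shapes[batch - 1]

    for name, t in config.traits.items():
        var_a = t.h2  # sigma_a^2 + sigma_e^2 normalized to 1
        var_e = 1.0 - t.h2
        var_b = t.hbatch / (1.0 - t.hbatch)  # so var_b/(1+var_b) = hbatch

        n_qtl = max(1, int(round(config.prop_qtl * config.n_snps)))
        qtl = rng.choice(config.n_snps, size=n_qtl, replace=False)
        beta = np.zeros(config.n_snps)
        beta[qtl] = rng.normal(size=n_qtl)
        a_raw = Mc @ beta
        if var_a > 0 and a_raw.var(ddof=1) > 0:
            scale = np.sqrt(var_a / a_raw.var(ddof=1))
            beta *= scale
            a = a_raw * scale
        else:
            beta[:] = 0.0
            a = np.zeros(n)

        b_levels = rng.normal(size=config.n_batches)
        b = b_levels[batch - 1]
        if var_b > 0 and b.var(ddof=1) > 0:
            s = np.sqrt(var_b / b.var(ddof=1))
            b_levels, b = b_levels * s, b * s
        else:
            b_levels = np.zeros(config.n_batches)
            b = np.zeros(n)

        e = _scale_to_var(rng.normal(size=n), var_e)

        sd_e = np.sqrt(var_e) if var_e > 0 else 1.0
        dvec = np.linspace(-1, 1, config.n_dim_classes) * config.fixed_effect_scale * sd_e
        pvec = np.linspace(-1, 1, config.n_parity_classes) * config.fixed_effect_scale * sd_e

        y = t.mean + dvec[dim_class - 1] + pvec[parity - 1] + a + b + e
        cow[name] = y

        u = a + b + e
        s_sig = config.spectral_signal
        if s_sig <= 0 or u.var(ddof=1) == 0:
            v = rng.normal(size=n)
        else:
            noise_var = u.var(ddof=1) * (1.0 - s_sig) / s_sig if s_sig < 1 else 0.0
            v = u + rng.normal(0, np.sqrt(noise_var), size=n) if noise_var > 0 else u.copy()
        v_std = (v - v.mean()) / max(v.std(ddof=1), 1e-12)
        load, mask = _trait_loadings(rng, p_wl)
        raw += np.outer(v_std, load * 0.25)

        snp_effects[name] = beta
        breeding_values[name] = a
        batch_effects[name] = b_levels
        dim_effects[name] = dvec
        parity_effects[name] = pvec
        realized_h2[name] = float(a.var(ddof=1) / (a.var(ddof=1) + e.var(ddof=1))) if var_a > 0 else 0.0
        realized_hb[name] = float(
            b.var(ddof=1) / (a.var(ddof=1) + b.var(ddof=1) + e.var(ddof=1))
        )
        masks[name] = mask
        latents[name] = v_std

    raw += rng.normal(0, config.channel_noise_sd, size=raw.shape)

    n_out = int(round(config.outlier_fraction * n))
    out_idx = rng.choice(n, size=n_out, replace=False) if n_out else np.array([], dtype=int)
    if n_out:
        signs = rng.choice([-1.0, 1.0], size=(n_out, p_wl))
        raw[out_idx] += config.outlier_offset * signs

    # two replicate rows per cow, differing only by replicate noise
    rep = np.repeat(raw, 2, axis=0)
    rep += rng.normal(0, config.replicate_noise_sd, size=rep.shape)
    ids2 = np.repeat(genotypes.sample_ids, 2)
    rep_tag = np.tile([1, 2], n)

    wavenumbers = np.linspace(5011, 925, p_wl)
    if config.emit == "transmittance":
        absorb = np.clip(0.5 + 0.08 * rep, 1e-3, None)
        values = 10.0 ** (-absorb)
    else:
        values = rep
    spectra = SpectraMatrix(values, wavenumbers, ids2, rep_tag)

    truth = SimTruth(
        snp_effects=snp_effects,
        breeding_values=breeding_values,
        batch_effects=batch_effects,
        dim_effects=dim_effects,
        parity_effects=parity_effects,
        realized_h2=realized_h2,
        realized_hbatch=realized_hb,
        loading_masks=masks,
        latent=latents,
        allele_freqs=np.array([]),
        outlier_ids=np.asarray(genotypes.sample_ids)[out_idx],
    )
    return cow, spectra, truth


def _parity_probs(k: int) -> np.ndarray:
    base = np.array([0.45, 0.27, 0.15, 0.13])
    if k == 4:
        return base
    w = 0.55 ** np.arange(k)
    return w / w.sum()


def simulate_dataset(config: SimConfig) -> SimBundle:
    """Run the full generator: pedigree -> genotypes -> phenotypes/spectra."""
    ped = simulate_pedigree(config)
    geno = simulate_genotypes(ped, config)
    cow, spectra, truth = simulate_phenotypes_and_spectra(geno, config)
    return SimBundle(config, ped, geno, cow, spectra, truth)
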