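"""File dialects, data alignment, configuration and the end-to-end driver.

Formats are deliberately plain: delimited text for cow tables, spectra,
dosages and pedigrees (plus PLINK-style .ped/.map for genotypes and HDF5 for
matrices), so that every artifact is inspectable and round-trips through
pandas/h5py.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._exceptions import ConfigError, DataError
from .animal_model import ChainConfig, gibbs_animal_model
from .boosting import GBMSearchSpace
from .cv import AnalysisData, run_experiment
from .kinship import GenotypeSet, KinshipBundle, Pedigree, build_kinship, genotype_qc
from .simulate import SimBundle, SimConfig, TraitTargets, simulate_dataset
from .spectra import SpectraMatrix, preprocess_pipeline

__all__ = [
    "dim_class",
    "parity_class",
    "read_cow_table",
    "write_cow_table",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_spectra_hdf5",
    "write_spectra_hdf5",
    "read_pedigree_csv",
    "write_pedigree_csv",
    "read_dosage_csv",
    "write_dosage_csv",
    "read_plink",
    "write_plink",
    "write_kinship_hdf5",
    "read_kinship_hdf5",
    "prepare_analysis_data",
    "ExperimentConfig",
    "RunManifest",
    "run_all",
]

DIM_CUTPOINTS = (60, 121, 181, 241, 301)


def dim_class(dim) -> np.ndarray:
    """Map days in milk to 6 classes: <60, 60-120, 121-180, 181-240, 241-300, >300."""
    dim = np.asarray(dim)
    if np.any(dim < 0):
        raise DataError("negative DIM encountered")
    return np.digitize(dim, DIM_CUTPOINTS) + 1


def parity_class(parity, max_class: int = 4) -> np.ndarray:
    """Top-coded parity classes 1, 2, 3, >=4."""
    parity = np.asarray(parity)
    if np.any(parity < 1):
        raise DataError("parity must be >= 1")
    return np.minimum(parity, max_class)


# ---------------------------------------------------------------- cow table

def write_cow_table(cow: pd.DataFrame, path) -> None:
    cow.to_csv(path, index=False)


def read_cow_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("animal", "herd", "batch", "dim", "parity"):
        if col not in df.columns:
            raise ConfigError(f"cow table missing required column {col!r}")
    return df


# ------------------------------------------------------------------ spectra

def write_spectra_csv(spectra: SpectraMatrix, path) -> None:
    df = pd.DataFrame(spectra.values,
                      columns=[f"{w:.4f}" for w in spectra.wavenumbers])
    df.insert(0, "animal", spectra.ids)
    df.insert(
        1,
        "replicate",
        spectra.replicate if spectra.replicate is not None
        else np.ones(spectra.n_samples, dtype=int),
    )
    df.to_csv(path, index=False)


def read_spectra_csv(path) -> SpectraMatrix:
    df = pd.read_csv(path)
    wl_cols = [c for c in df.columns if c not in ("animal", "replicate")]
    return SpectraMatrix(
        values=df[wl_cols].to_numpy(dtype=float),
        wavenumbers=np.array([float(c) for c in wl_cols]),
        ids=df["animal"].to_numpy(),
        replicate=df["replicate"].to_numpy() if "replicate" in df else None,
    )


def write_spectra_hdf5(spectra: SpectraMatrix, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=spectra.values)
        f.create_dataset("wavenumbers", data=spectra.wavenumbers)
        f.create_dataset("ids", data=np.asarray(spectra.ids, dtype=np.int64))
        if spectra.replicate is not None:
            f.create_dataset(
                "replicate", data=np.asarray(spectra.replicate, dtype=np.int64)
            )
        f.attrs["standardized"] = spectra.standardized


def read_spectra_hdf5(path) -> SpectraMatrix:
    with h5py.File(path, "r") as f:
        return SpectraMatrix(
            values=f["values"][:],
            wavenumbers=f["wavenumbers"][:],
            ids=f["ids"][:],
            replicate=f["replicate"][:] if "replicate" in f else None,
            standardized=bool(f.attrs.get("standardized", False)),
        )


# ----------------------------------------------------------------- pedigree

def write_pedigree_csv(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def read_pedigree_csv(path) -> Pedigree:
    df = pd.read_csv(path)
    return Pedigree(
        df["animal"].to_numpy(), df["sire"].to_numpy(), df["dam"].to_numpy()
    )


# ---------------------------------------------------------------- genotypes

def write_dosage_csv(genotypes: GenotypeSet, path, meta_path=None) -> None:
    df = pd.DataFrame(
        genotypes.dosages, columns=genotypes.snp_meta["snp"].tolist()
    )
    df.insert(0, "animal", genotypes.sample_ids)
    df.to_csv(path, index=False)
    if meta_path is not None:
        genotypes.snp_meta.to_csv(meta_path, index=False)


def read_dosage_csv(path, meta_path=None) -> GenotypeSet:
    df = pd.read_csv(path)
    snp_cols = [c for c in df.columns if c != "animal"]
    if meta_path is not None:
        meta = pd.read_csv(meta_path)
    else:
        meta = pd.DataFrame(
            {"snp": snp_cols, "chrom": 1, "pos": np.arange(len(snp_cols)),
             "a1": "A", "a2": "B"}
        )
    D = df[snp_cols].to_numpy(dtype=float)
    imputed = bool(np.any(~np.isnan(D) & (D != np.round(D))))
    return GenotypeSet(D, meta, df["animal"].to_numpy(), imputed=imputed)


def write_plink(genotypes: GenotypeSet, prefix) -> None:
    """PLINK-style text dialect: <prefix>.ped and <prefix>.map."""
    prefix = Path(prefix)
    meta = genotypes.snp_meta
    with open(f"{prefix}.map", "w") as f:
        for _, r in meta.iterrows():
            f.write(f"{r['chrom']}\t{r['snp']}\t0\t{r['pos']}\n")
    code = {0.0: "A A", 1.0: "A B", 2.0: "B B"}
    with open(f"{prefix}.ped", "w") as f:
        for i, sid in enumerate(genotypes.sample_ids):
            row = genotypes.dosages[i]
            alleles = " ".join(
                "0 0" if np.isnan(d) else code[float(d)] for d in row
            )
            f.write(f"FAM {sid} 0 0 2 -9 {alleles}\n")


def read_plink(prefix) -> GenotypeSet:
    prefix = Path(prefix)
    meta = pd.read_csv(
        f"{prefix}.map", sep="\t", header=None,
        names=["chrom", "snp", "cm", "pos"],
    )[["snp", "chrom", "pos"]]
    meta["a1"], meta["a2"] = "A", "B"
    ids, rows = [], []
    with open(f"{prefix}.ped") as f:
        for line in f:
            parts = line.split()
            ids.append(int(parts[1]))
            alleles = parts[6:]
            d = np.empty(len(alleles) // 2)
            for j in range(d.size):
                a, b = alleles[2 * j], alleles[2 * j + 1]
                if a == "0" or b == "0":
                    d[j] = np.nan
                else:
                    d[j] = (a == "B") + (b == "B")
            rows.append(d)
    return GenotypeSet(np.array(rows), meta, np.array(ids))


# ----------------------------------------------------------------- matrices

def write_kinship_hdf5(bundle: KinshipBundle, path) -> None:
    with h5py.File(path, "w") as f:
        for name in ("A", "A22", "G", "Hinv"):
            f.create_dataset(name, data=getattr(bundle, name))
        f.create_dataset("id_order", data=bundle.id_order.astype(np.int64))
        f.create_dataset(
            "genotyped_ids", data=np.asarray(bundle.genotyped_ids, dtype=np.int64)
        )


def read_kinship_hdf5(path) -> KinshipBundle:
    with h5py.File(path, "r") as f:
        return KinshipBundle(
            A=f["A"][:], A22=f["A22"][:], G=f["G"][:], Hinv=f["Hinv"][:],
            id_order=f["id_order"][:], genotyped_ids=f["genotyped_ids"][:],
        )


# ---------------------------------------------------------------- alignment

def prepare_analysis_data(
    cow_table: pd.DataFrame,
    spectra: SpectraMatrix,
    genotypes: GenotypeSet,
    pedigree: Pedigree,
    alpha: float = 0.05,
    maf_min: float = 0.05,
    hwe_p: float = 1e-5,
    call_rate: float = 0.95,
    from_transmittance: bool = True,
) -> tuple[AnalysisData, KinshipBundle, dict]:
    """Run spectra preprocessing and genotype QC, then inner-join on cow id.

    Returns the aligned analysis bundle, the kinship matrices and an
    attrition log (cows per source before/after each step).
    """
    trait_cols = [
        c for c in cow_table.columns
        if c not in ("animal", "herd", "batch", "dim", "parity",
                     "dim_class", "parity_class")
    ]
    spec_clean, removed = preprocess_pipeline(
        spectra, alpha=alpha, from_transmittance=from_transmittance
    )
    geno_qc, qc_report = genotype_qc(
        genotypes, maf_min=maf_min, hwe_p=hwe_p, call_rate=call_rate
    )
    kin = build_kinship(pedigree, geno_qc)

    ids = np.intersect1d(
        np.intersect1d(cow_table["animal"].to_numpy(), spec_clean.ids),
        geno_qc.sample_ids,
    )
    cow = cow_table.set_index("animal").loc[ids].reset_index()
    spec_pos = {a: i for i, a in enumerate(spec_clean.ids)}
    S = spec_clean.values[[spec_pos[a] for a in ids]]
    geno_pos = {a: i for i, a in enumerate(geno_qc.sample_ids)}
    gidx = np.array([geno_pos[a] for a in ids])
    snp = geno_qc.dosages[gidx]
    G_sub = kin.G[np.ix_(gidx, gidx)]

    data = AnalysisData(
        ids=ids,
        spectra=S,
        dim_class=dim_class(cow["dim"].to_numpy()),
        parity_class=parity_class(cow["parity"].to_numpy()),
        batch=cow["batch"].to_numpy(),
        herd=cow["herd"].to_numpy(),
        traits=cow[trait_cols],
        snp=snp,
        G=G_sub,
        wavenumbers=spec_clean.wavenumbers,
    )
    attrition = {
        "cows_in_cow_table": int(len(cow_table)),
        "spectra_rows_in": int(spectra.n_samples),
        "cows_after_spectra_qc": int(spec_clean.n_samples),
        "spectra_outliers_removed": int(removed.size),
        "genotyped_in": int(genotypes.n_samples),
        "genotyped_after_qc": int(geno_qc.n_samples),
        "snps_in": qc_report.n_snps_in,
        "snps_after_qc": qc_report.n_snps_out,
        "analysis_cows": int(ids.size),
        "genotype_qc": dataclasses.asdict(qc_report),
    }
    return data, kin, attrition


# ------------------------------------------------------------ configuration

@dataclass
class ExperimentConfig:
    """One YAML document driving the full pipeline."""

    simulate: dict | None = None
    inputs: dict | None = None
    qc: dict = field(default_factory=dict)
    chain: dict = field(default_factory=dict)
    gbm: dict = field(default_factory=dict)
    experiment: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "ftirpred_out"

    def __post_init__(self) -> None:
        if self.simulate is None and self.inputs is None:
            raise ConfigError("config needs either a 'simulate' or 'inputs' block")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as f:
            doc = yaml.safe_load(f)
        return cls(**doc)

    def sim_config(self) -> SimConfig:
        block = dict(self.simulate or {})
        traits = block.pop("traits", None)
        kwargs = dict(block)
        if traits is not None:
            kwargs["traits"] = {
                name: TraitTargets(**t) for name, t in traits.items()
            }
        if "herd_sizes" in kwargs:
            kwargs["herd_sizes"] = tuple(kwargs["herd_sizes"])
        kwargs.setdefault("rng_seed", self.seed)
        return SimConfig(**kwargs)


@dataclass
class RunManifest:
    """Reproducibility record of one end-to-end run."""

    config: dict
    version: str
    master_seed: int
    attrition: dict
    stage_seeds: dict
    started: float
    finished: float = 0.0

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(dataclasses.asdict(self), f, indent=2, default=str)


def _load_inputs(inputs: dict):
    cow = read_cow_table(inputs["cow_table"])
    spectra_path = Path(inputs["spectra"])
    if spectra_path.suffix in (".h5", ".hdf5"):
        spectra = read_spectra_hdf5(spectra_path)
    else:
        spectra = read_spectra_csv(spectra_path)
    if "genotypes_prefix" in inputs:
        geno = read_plink(inputs["genotypes_prefix"])
    else:
        geno = read_dosage_csv(inputs["genotypes"], inputs.get("snp_meta"))
    ped = read_pedigree_csv(inputs["pedigree"])
    return cow, spectra, geno, ped


def run_all(config: ExperimentConfig) -> RunManifest:
    """simulate-or-load -> QC -> kinship -> variance components -> factorial."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = time.time()

    exp = dict(config.experiment)
    models = exp.get("models", ["M1", "M2", "M3", "M4"])
    needs_geno = any(m in ("M3", "M4") for m in models) or "batch_out" in exp.get(
        "schemes", ["tenfold", "batch_out", "herd_out"]
    )
    if config.inputs is not None and needs_geno and not (
        "genotypes" in config.inputs or "genotypes_prefix" in config.inputs
    ):
        raise ConfigError("models M3/M4 or batch-out CV requested without genotypes")

    if config.simulate is not None:
        bundle = simulate_dataset(config.sim_config())
        cow, spectra, geno, ped = (
            bundle.cow_table, bundle.spectra, bundle.genotypes, bundle.pedigree
        )
        from_transmittance = bundle.config.emit == "transmittance"
    else:
        cow, spectra, geno, ped = _load_inputs(config.inputs)
        from_transmittance = bool(config.inputs.get("transmittance", True))

    qc = dict(alpha=0.05, maf_min=0.05, hwe_p=1e-5, call_rate=0.95)
    qc.update(config.qc)
    data, kin, attrition = prepare_analysis_data(
        cow, spectra, geno, ped,
        from_transmittance=from_transmittance, **qc
    )

    chain_kwargs = dict(n_iter=50_000, burn_in=10_000, thin=5, seed=config.seed)
    chain_kwargs.update(config.chain)
    chain = ChainConfig(**chain_kwargs)
    cow_for_gibbs = cow[cow["animal"].isin(data.ids)].copy()
    cow_for_gibbs["dim_class"] = dim_class(cow_for_gibbs["dim"].to_numpy())
    cow_for_gibbs["parity_class"] = parity_class(cow_for_gibbs["parity"].to_numpy())
    genetics_rows = []
    traits = exp.get("traits", list(data.traits.columns))
    for trait in traits:
        summ = gibbs_animal_model(cow_for_gibbs, kin, trait, chain=chain)
        genetics_rows.append(
            {
                "trait": trait,
                "sigma2_a": summ.var_mean[0],
                "sigma2_batch": summ.var_mean[1],
                "sigma2_e": summ.var_mean[2],
                "h2": summ.h2_mean,
                "h2_sd": summ.h2_sd,
                "hbatch": summ.hbatch_mean,
                "hbatch_sd": summ.hbatch_sd,
                "geweke_p_sigma2_a": summ.geweke_p.get("sigma2_a", np.nan),
                "converged": summ.converged,
            }
        )
    genetics = pd.DataFrame(genetics_rows)
    genetics.to_csv(outdir / "variance_components.csv", index=False)

    gbm_space = GBMSearchSpace(**config.gbm) if config.gbm else None
    result = run_experiment(
        data,
        methods=tuple(exp.get("methods", ("bayesb", "gbm"))),
        models=tuple(models),
        schemes=tuple(exp.get("schemes", ("tenfold", "batch_out", "herd_out"))),
        traits=traits,
        seed=config.seed,
        bayesb_params=exp.get("bayesb"),
        gbm_space=gbm_space,
    )
    result.results.to_csv(outdir / "cv_results.csv", index=False)
    result.summary().to_csv(outdir / "cv_summary.csv", index=False)
    result.rd_table().to_csv(outdir / "rd_table.csv", index=False)

    manifest = RunManifest(
        config=dataclasses.asdict(config),
        version=__version__,
        master_seed=config.seed,
        attrition=attrition,
        stage_seeds={"chain": chain.seed, "experiment": config.seed},
        started=started,
        finished=time.time(),
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest
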