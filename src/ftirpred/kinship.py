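"""Genotype QC and pedigree/genomic relationship matrices.

Implements the single-step GBLUP kinship machinery: the numerator
relationship matrix A from a pedigree (tabular method), the genomic
relationship matrix G from 0/1/2 SNP dosages (VanRaden method 1: columns
centered by twice the observed allele frequency, quadratic form scaled by
2*sum p_j(1-p_j)), and the combined inverse

    H^-1 = A^-1 + [[0, 0], [0, G^-1 - A22^-1]]

with the correction applied on the genotyped block of A's ordering.  G is
blended with a small share of A22 before inversion to guarantee positive
definiteness, as is standard ssGBLUP practice.

SNP/sample quality control follows fixed, reported filter order:
non-autosomal SNPs -> SNP call rate -> MAF -> Hardy-Weinberg -> sample call
rate, after which remaining missing dosages are mean-imputed to 2p_j.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import ConfigError, DataError, NumericalError, PedigreeError

__all__ = [
    "Pedigree",
    "GenotypeSet",
    "KinshipBundle",
    "QCReport",
    "genotype_qc",
    "build_A",
    "build_G",
    "blend_G",
    "build_Hinv",
    "build_kinship",
    "hwe_test_pvalue",
]


@dataclass
class Pedigree:
    """Ordered pedigree records (animal, sire, dam); 0 means unknown parent."""

    animal: np.ndarray
    sire: np.ndarray
    dam: np.ndarray

    def __post_init__(self) -> None:
        self.animal = np.asarray(self.animal, dtype=np.int64)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if not (self.animal.shape == self.sire.shape == self.dam.shape):
            raise PedigreeError("animal/sire/dam columns must have equal length")
        pos = {a: i for i, a in enumerate(self.animal)}
        if len(pos) != self.animal.size:
            raise PedigreeError("duplicate animal ids in pedigree")
        for i, (s, d) in enumerate(zip(self.sire, self.dam)):
            for parent in (s, d):
                if parent == 0:
                    continue
                if parent not in pos:
                    raise PedigreeError(f"unknown parent id {parent}")
                if pos[parent] >= i:
                    raise PedigreeError(
                        f"parent {parent} does not precede offspring "
                        f"{self.animal[i]} (cycle or bad ordering)"
                    )

    def __len__(self) -> int:
        return self.animal.size

    def index_of(self, ids) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.animal)}
        return np.array([pos[int(i)] for i in np.asarray(ids)], dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"animal": self.animal, "sire": self.sire, "dam": self.dam}
        )


@dataclass
class GenotypeSet:
    """SNP dosages (0/1/2, NaN = missing) with per-SNP metadata.

    ``snp_meta`` carries columns snp, chrom, pos (chrom 0 flags
    non-autosomal markers).  After QC imputation dosages become fractional
    and ``imputed`` is set.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: np.ndarray
    imputed: bool = False

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.dosages.ndim != 2:
            raise ConfigError("dosage matrix must be 2-D")
        if len(self.snp_meta) != self.dosages.shape[1]:
            raise ConfigError("snp_meta length must equal dosage columns")
        if self.sample_ids.shape[0] != self.dosages.shape[0]:
            raise ConfigError("one sample id per dosage row is required")
        if not self.imputed:
            vals = self.dosages[~np.isnan(self.dosages)]
            if vals.size and not np.all(np.isin(vals, [0.0, 1.0, 2.0])):
                raise ConfigError("dosages must be 0/1/2 or missing (NaN)")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


@dataclass
class QCReport:
    """Per-filter attrition counts from genotype QC."""

    n_snps_in: int
    n_removed_nonautosomal: int
    n_removed_snp_callrate: int
    n_removed_maf: int
    n_removed_hwe: int
    n_snps_out: int
    n_samples_in: int
    n_removed_sample_callrate: int
    n_samples_out: int


@dataclass
class KinshipBundle:
    """A, A22, G and H^-1 over a shared animal ordering."""

    A: np.ndarray
    A22: np.ndarray
    G: np.ndarray
    Hinv: np.ndarray
    id_order: np.ndarray
    genotyped_ids: np.ndarray


def hwe_test_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Hardy-Weinberg equilibrium P-value for one biallelic SNP.

    Exact conditional test (two-sided, summing probabilities of heterozygote
    counts no more likely than the observed one) when total genotype count is
    below 1000, otherwise the 1-df chi-square goodness-of-fit test.
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    if n < 1000:
        return _hwe_exact(n_aa, n_ab, n_bb)
    n_a = 2 * n_aa + n_ab
    p = n_a / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = np.sum((obs - exp) ** 2 / exp)
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    # Exact HWE test on the conditional distribution of heterozygote counts
    # given allele counts; probabilities computed by the usual two-sided
    # recurrence, starting from the mode.
    n = n_aa + n_ab + n_bb
    n_rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    het_parity = n_rare % 2
    hets = np.arange(het_parity, n_rare + 1, 2)
    probs = np.zeros(hets.size)
    # unnormalized log-probabilities via the hypergeometric-like pmf
    from scipy.special import gammaln

    n_common = 2 * n - n_rare
    for i, h in enumerate(hets):
        ra = (n_rare - h) // 2
        ca = (n_common - h) // 2
        probs[i] = (
            gammaln(n + 1)
            - gammaln(ra + 1)
            - gammaln(h + 1)
            - gammaln(ca + 1)
            + h * np.log(2)
        )
    probs = np.exp(probs - probs.max())
    probs /= probs.sum()
    obs = probs[hets == n_ab][0]
    return float(min(1.0, probs[probs <= obs + 1e-12].sum()))


def genotype_qc(
    genotypes: GenotypeSet,
    maf_min: float = 0.05,
    hwe_p: float = 1e-5,
    call_rate: float = 0.95,
) -> tuple[GenotypeSet, QCReport]:
    """SNP and sample quality control with fixed filter order.

    Filters, in order: non-autosomal SNPs; SNP call rate < ``call_rate``;
    MAF strictly below ``maf_min``; HWE P <= ``hwe_p``; sample call rate
    < ``call_rate``.  Surviving missing dosages are imputed to 2p_j.
    """
    D = genotypes.dosages.copy()
    meta = genotypes.snp_meta.reset_index(drop=True)
    n_snps_in, n_samples_in = D.shape[1], D.shape[0]

    # 1) autosomes only (chrom 0 = non-autosomal flag)
    auto = meta["chrom"].to_numpy() > 0
    n_nonauto = int((~auto).sum())
    D, meta = D[:, auto], meta.loc[auto].reset_index(drop=True)

    # 2) SNP call rate
    cr = 1.0 - np.isnan(D).mean(axis=0)
    keep = cr >= call_rate
    n_cr = int((~keep).sum())
    D, meta = D[:, keep], meta.loc[keep].reset_index(drop=True)

    # 3) MAF (strict "lower than")
    with np.errstate(invalid="ignore"):
        p = np.nanmean(D, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= maf_min
    n_maf = int((~keep).sum())
    D, meta = D[:, keep], meta.loc[keep].reset_index(drop=True)

    # 4) HWE (removal at P <= threshold, inclusive)
    pvals = np.empty(D.shape[1])
    for j in range(D.shape[1]):
        col = D[:, j]
        col = col[~np.isnan(col)]
        pvals[j] = hwe_test_pvalue(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
    keep = pvals > hwe_p
    n_hwe = int((~keep).sum())
    D, meta = D[:, keep], meta.loc[keep].reset_index(drop=True)

    # 5) sample call rate
    if D.shape[1] == 0:
        report = QCReport(
            n_snps_in, n_nonauto, n_cr, n_maf, n_hwe, 0, n_samples_in, 0, n_samples_in
        )
        raise DataError(f"all SNPs removed by QC: {report}")
    sample_cr = 1.0 - np.isnan(D).mean(axis=1)
    keep_s = sample_cr >= call_rate
    n_scr = int((~keep_s).sum())
    D = D[keep_s]
    sample_ids = genotypes.sample_ids[keep_s]

    # impute remaining missing to 2p_j (keeps allele frequencies)
    p = np.nanmean(D, axis=0) / 2.0
    nan_r, nan_c = np.where(np.isnan(D))
    D[nan_r, nan_c] = 2.0 * p[nan_c]

    report = QCReport(
        n_snps_in=n_snps_in,
        n_removed_nonautosomal=n_nonauto,
        n_removed_snp_callrate=n_cr,
        n_removed_maf=n_maf,
        n_removed_hwe=n_hwe,
        n_snps_out=D.shape[1],
        n_samples_in=n_samples_in,
        n_removed_sample_callrate=n_scr,
        n_samples_out=D.shape[0],
    )
    if D.shape[0] == 0:
        raise DataError(f"all samples removed by QC: {report}")
    return GenotypeSet(D, meta, sample_ids, imputed=True), report


def build_A(pedigree: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular (recursive) method."""
    n = len(pedigree)
    pos = {a: i for i, a in enumerate(pedigree.animal)}
    si = np.array([pos.get(s, -1) for s in pedigree.sire])
    di = np.array([pos.get(d, -1) for d in pedigree.dam])
    A = np.zeros((n, n))
    for i in range(n):
        s, d = si[i], di[i]
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    return A


def build_G(genotypes: GenotypeSet) -> np.ndarray:
    """Genomic relationship matrix, VanRaden method 1.

    Columns of the dosage matrix are centered by 2p_j (observed allele
    frequency of the dose-counted allele) and the quadratic form is scaled
    by 2*sum p_j (1 - p_j).
    """
    M = np.asarray(genotypes.dosages, dtype=float)
    if np.isnan(M).any():
        raise DataError("G requires complete dosages; run genotype_qc first")
    p = M.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom == 0:
        raise DataError("all SNPs monomorphic: zero denominator in G")
    Z = M - 2.0 * p
    return (Z @ Z.T) / denom


def blend_G(G: np.ndarray, A22: np.ndarray, weight: float = 0.95) -> np.ndarray:
    """Blend G with A22 (default 0.95 G + 0.05 A22) to guarantee invertibility."""
    return weight * G + (1.0 - weight) * A22


def build_Hinv(
    A: np.ndarray,
    genotyped_idx: np.ndarray,
    G: np.ndarray,
    blend_weight: float = 0.95,
) -> np.ndarray:
    """H^-1 = A^-1 plus the genotyped-block correction G_b^-1 - A22^-1."""
    genotyped_idx = np.asarray(genotyped_idx, dtype=np.int64)
    Ainv = np.linalg.inv(A)
    if genotyped_idx.size == 0:
        return Ainv
    A22 = A[np.ix_(genotyped_idx, genotyped_idx)]
    Gb = blend_G(G, A22, blend_weight)
    try:
        Gb_inv = np.linalg.inv(Gb)
    except np.linalg.LinAlgError as err:
        raise NumericalError(
            f"blended G singular (cond={np.linalg.cond(Gb):.3e})"
        ) from err
    A22_inv = np.linalg.inv(A22)
    Hinv = Ainv.copy()
    Hinv[np.ix_(genotyped_idx, genotyped_idx)] += Gb_inv - A22_inv
    return Hinv


def build_kinship(
    pedigree: Pedigree,
    genotypes: GenotypeSet,
    blend_weight: float = 0.95,
) -> KinshipBundle:
    """Assemble A, A22, G and H^-1 on the pedigree's animal ordering."""
    A = build_A(pedigree)
    gidx = pedigree.index_of(genotypes.sample_ids)
    A22 = A[np.ix_(gidx, gidx)]
    G = build_G(genotypes)
    Hinv = build_Hinv(A, gidx, G, blend_weight=blend_weight)
    return KinshipBundle(
        A=A,
        A22=A22,
        G=G,
        Hinv=Hinv,
        id_order=pedigree.animal.copy(),
        genotyped_ids=np.asarray(genotypes.sample_ids),
    )
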