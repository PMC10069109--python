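import math

import numpy as np
import pandas as pd
import pytest

import ftirpred as fp
from ftirpred._exceptions import DataError, PedigreeError
from ftirpred.kinship import (
    GenotypeSet,
    Pedigree,
    blend_G,
    build_A,
    build_G,
    build_Hinv,
    genotype_qc,
    hwe_test_pvalue,
)


def geno(dosages, chrom=None):
    D = np.asarray(dosages, dtype=float)
    m = D.shape[1]
    meta = pd.DataFrame(
        {
            "snp": [f"s{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else np.ones(m, dtype=int),
            "pos": np.arange(m),
            "a1": "A",
            "a2": "B",
        }
    )
    return GenotypeSet(D, meta, np.arange(D.shape[0]) + 1)


# ------------------------------------------------------------------ QC

class TestGenotypeQC:
    def test_maf_boundary_strictly_lower(self):
        n = 500
        col_049 = np.r_[np.ones(49), np.zeros(n - 49)]  # p = 0.049
        col_050 = np.r_[np.ones(50), np.zeros(n - 50)]  # p = 0.050
        keeper = np.tile([0, 1, 2, 1], n // 4)  # common, in HWE-ish balance
        g = geno(np.column_stack([col_049, col_050, keeper]))
        out, report = genotype_qc(g)
        kept = set(out.snp_meta["snp"])
        assert "s0" not in kept and "s1" in kept
        assert report.n_removed_maf == 1

    def test_hwe_violation_removed(self):
        n = 400
        violer = np.r_[np.zeros(n // 2), np.full(n // 2, 2.0)]  # no hets at p=0.5
        np.random.default_rng(0).shuffle(violer)
        fine = np.tile([0, 1, 1, 2], n // 4)
        g = geno(np.column_stack([violer, fine]))
        assert hwe_test_pvalue(n // 2, 0, n // 2) <= 1e-5
        out, report = genotype_qc(g)
        assert report.n_removed_hwe == 1
        assert list(out.snp_meta["snp"]) == ["s1"]

    def test_nonautosomal_removed_first(self):
        base = np.tile([0, 1, 1, 2], 25)
        g = geno(np.column_stack([base, base]), chrom=[0, 1])
        out, report = genotype_qc(g)
        assert report.n_removed_nonautosomal == 1
        assert out.n_snps == 1

    def test_snp_and_sample_call_rate(self):
        rng = np.random.default_rng(1)
        n, m = 200, 30
        D = rng.choice([0.0, 1.0, 2.0], size=(n, m), p=[0.25, 0.5, 0.25])
        D[: n // 10, 0] = np.nan  # SNP 0 call rate 0.90 -> removed
        D[0, 1 : 1 + int(0.2 * m)] = np.nan  # sample 0 call rate 0.80 -> removed
        g = geno(D)
        out, report = genotype_qc(g)
        assert report.n_removed_snp_callrate == 1
        assert report.n_removed_sample_callrate == 1
        assert 1 not in set(out.sample_ids)
        assert not np.isnan(out.dosages).any()  # imputation completed

    def test_all_removed_raises(self):
        g = geno(np.zeros((50, 2)))  # monomorphic -> MAF filter kills all
        with pytest.raises(DataError):
            genotype_qc(g)


def _hwe_exact_oracle(n_aa, n_ab, n_bb):
    """Exact HWE p-value by integer-factorial enumeration."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab

    def prob(nab):
        naa = (n_a - nab) // 2
        nbb = n - naa - nab
        if naa < 0 or nbb < 0:
            return 0.0
        num = (
            math.factorial(n)
            * 2**nab
            * math.factorial(n_a)
            * math.factorial(2 * n - n_a)
        )
        den = (
            math.factorial(naa)
            * math.factorial(nab)
            * math.factorial(nbb)
            * math.factorial(2 * n)
        )
        return num / den

    cands = [h for h in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)]
    probs = {h: prob(h) for h in cands}
    obs = probs[n_ab]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-12))


@pytest.mark.parametrize(
    "counts", [(5, 20, 25), (10, 10, 10), (0, 5, 45), (30, 40, 30)]
)
def test_hwe_exact_matches_enumeration_oracle(counts):
    assert hwe_test_pvalue(*counts) == pytest.approx(
        _hwe_exact_oracle(*counts), rel=1e-6
    )


# ------------------------------------------------------------------ A matrix

class TestBuildA:
    def test_unrelated_founders(self):
        ped = Pedigree([1, 2], [0, 0], [0, 0])
        np.testing.assert_allclose(build_A(ped), np.eye(2))

    def test_parent_offspring(self):
        ped = Pedigree([1, 2, 3], [0, 0, 1], [0, 0, 2])
        A = build_A(ped)
        assert A[2, 2] == 1.0
        assert A[0, 2] == 0.5 and A[1, 2] == 0.5

    def test_full_sibs(self):
        ped = Pedigree([1, 2, 3, 4], [0, 0, 1, 1], [0, 0, 2, 2])
        A = build_A(ped)
        assert A[2, 3] == 0.5

    def test_bad_ordering_rejected(self):
        with pytest.raises(PedigreeError):
            Pedigree([1, 2], [2, 0], [0, 0])

    def test_matches_gene_dropping_oracle(self, rng):
        n, n_founders, n_drops = 30, 10, 100_000
        sire = np.zeros(n, dtype=int)
        dam = np.zeros(n, dtype=int)
        for i in range(n_founders, n):
            s, d = rng.choice(i, size=2, replace=False)
            sire[i], dam[i] = s + 1, d + 1
        ped = Pedigree(np.arange(1, n + 1), sire, dam)
        A = build_A(ped)

        # gene-drop: founders carry unique allele labels; offspring inherit
        # one random parental allele; relationship = 2 * P(IBD)
        alleles = np.zeros((n_drops, n, 2), dtype=np.int32)
        for i in range(n):
            if sire[i] == 0:
                alleles[:, i, 0] = 2 * i
                alleles[:, i, 1] = 2 * i + 1
            else:
                s, d = sire[i] - 1, dam[i] - 1
                pick = rng.integers(0, 2, size=n_drops)
                alleles[:, i, 0] = alleles[np.arange(n_drops), s, pick]
                pick = rng.integers(0, 2, size=n_drops)
                alleles[:, i, 1] = alleles[np.arange(n_drops), d, pick]
        Ahat = np.empty((n, n))
        for i in range(n):
            for j in range(i, n):
                m = sum(
                    (alleles[:, i, a] == alleles[:, j, b]).mean()
                    for a in (0, 1)
                    for b in (0, 1)
                )
                Ahat[i, j] = Ahat[j, i] = m / 2.0
        assert np.max(np.abs(A - Ahat)) < 0.02

    def test_simulated_pedigrees_positive_definite(self):
        for seed in range(10):
            cfg = fp.SimConfig(
                n_cows=40, n_snps=10, n_wavelengths=10, n_batches=2,
                herd_sizes=(30, 10), rng_seed=seed,
            )
            ped = fp.simulate_pedigree(cfg)
            np.linalg.cholesky(build_A(ped))  # raises if not PD


# ------------------------------------------------------------------ G matrix

class TestBuildG:
    def test_hand_computation_two_animals(self):
        g = geno([[0.0], [2.0]])
        G = build_G(g)
        np.testing.assert_allclose(G, [[2.0, -2.0], [-2.0, 2.0]])

    def test_all_heterozygous_gives_zero(self):
        g = geno(np.ones((4, 3)))
        np.testing.assert_allclose(build_G(g), 0.0)

    def test_matches_double_loop_oracle(self, rng):
        D = rng.choice([0.0, 1.0, 2.0], size=(10, 50))
        g = geno(D)
        G = build_G(g)
        p = D.mean(axis=0) / 2
        denom = 2 * np.sum(p * (1 - p))
        oracle = np.zeros((10, 10))
        for i in range(10):
            for j in range(10):
                oracle[i, j] = sum(
                    (D[i, k] - 2 * p[k]) * (D[j, k] - 2 * p[k])
                    for k in range(50)
                ) / denom
        np.testing.assert_allclose(G, oracle, atol=1e-10)

    def test_monomorphic_error(self):
        with pytest.raises(DataError):
            build_G(geno(np.full((5, 4), 2.0)))

    def test_mean_diagonal_near_one_under_hwe(self):
        cfg = fp.SimConfig(
            n_cows=200, n_snps=2000, n_wavelengths=10, n_batches=2,
            herd_sizes=(150, 50), n_generations=1, rng_seed=2,
        )
        ped = fp.simulate_pedigree(cfg)
        g = fp.simulate_genotypes(ped, cfg)
        G = build_G(g)
        assert abs(np.diag(G).mean() - 1.0) < 0.05


# ------------------------------------------------------------------ H inverse

class TestBuildHinv:
    def _pedigree(self, rng, n=12, founders=5):
        sire = np.zeros(n, dtype=int)
        dam = np.zeros(n, dtype=int)
        for i in range(founders, n):
            s, d = rng.choice(i, size=2, replace=False)
            sire[i], dam[i] = s + 1, d + 1
        return Pedigree(np.arange(1, n + 1), sire, dam)

    def test_no_genotyped_animals(self, rng):
        ped = self._pedigree(rng)
        A = build_A(ped)
        Hinv = build_Hinv(A, np.array([], dtype=int), np.empty((0, 0)))
        np.testing.assert_allclose(Hinv, np.linalg.inv(A), atol=1e-10)

    def test_G_equals_A22_cancels(self, rng):
        ped = self._pedigree(rng)
        A = build_A(ped)
        gidx = np.arange(6, 12)
        A22 = A[np.ix_(gidx, gidx)]
        Hinv = build_Hinv(A, gidx, A22)
        np.testing.assert_allclose(Hinv, np.linalg.inv(A), atol=1e-8)

    def test_matches_dense_oracle(self, rng):
        # oracle: assemble H itself blockwise, then invert
        ped = self._pedigree(rng)
        A = build_A(ped)
        gidx = np.arange(6, 12)
        ng = np.arange(6)
        D = rng.choice([0.0, 1.0, 2.0], size=(6, 40))
        G = build_G(geno(D))
        A22 = A[np.ix_(gidx, gidx)]
        Gb = blend_G(G, A22)
        A11 = A[np.ix_(ng, ng)]
        A12 = A[np.ix_(ng, gidx)]
        A22i = np.linalg.inv(A22)
        H = np.zeros_like(A)
        H[np.ix_(ng, ng)] = A11 + A12 @ A22i @ (Gb - A22) @ A22i @ A12.T
        H[np.ix_(ng, gidx)] = A12 @ A22i @ Gb
        H[np.ix_(gidx, ng)] = Gb @ A22i @ A12.T
        H[np.ix_(gidx, gidx)] = Gb
        oracle = np.linalg.inv(H)
        Hinv = build_Hinv(A, gidx, G)
        np.testing.assert_allclose(Hinv, oracle, atol=1e-8)
        np.testing.assert_allclose(Hinv, Hinv.T, atol=1e-10)
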