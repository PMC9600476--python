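"""Genotype QC, the VanRaden GRM, and the Mantel permutation test."""

import numpy as np
import pytest

from holoherit import InputError, compute_grm, mantel_test, qc_genotypes
from holoherit.genomics import RelationshipMatrix
from holoherit.simulate import SimulationConfig, simulate_genotypes

from conftest import make_genotypes


class TestQC:
    def test_monomorphic_snp_dropped(self):
        geno = make_genotypes([[0, 1], [0, 2], [0, 1]])
        out, report = qc_genotypes(geno, maf_min=0.05, call_rate_min=0.9)
        assert out.snp_ids == ["snp1"]
        assert report.n_dropped_maf == 1

    def test_call_rate_boundary_is_strict(self):
        """Call rate exactly 0.8 fails a 0.8 threshold ('greater than')."""
        col = [1.0] * 8 + [np.nan, np.nan]
        other = [0, 1, 2, 0, 1, 2, 0, 1, 2, 0]
        geno = make_genotypes(np.column_stack([col, other]))
        out, report = qc_genotypes(geno, maf_min=0.05, call_rate_min=0.8)
        assert out.snp_ids == ["snp1"]
        assert report.n_dropped_call_rate == 1

    def test_mean_imputation_fills_survivors(self):
        col = [0.0, 2.0, np.nan, 2.0, 0.0, 2.0, 0.0, 2.0, 0.0, 2.0]
        geno = make_genotypes(np.column_stack([col]))
        out, report = qc_genotypes(geno, maf_min=0.05, call_rate_min=0.5)
        assert report.n_imputed_entries == 1
        assert out.dosage[2, 0] == pytest.approx(np.nanmean(col))

    def test_all_dropped_raises_with_tally(self):
        geno = make_genotypes([[0, 0], [0, 0], [0, 0]])
        with pytest.raises(InputError, match="MAF"):
            qc_genotypes(geno)

    def test_matches_bruteforce_filter(self):
        """Survivors equal an independent one-pass filter with both rules."""
        rng = np.random.default_rng(11)
        X = rng.binomial(2, rng.uniform(0.02, 0.5, 200), size=(50, 200)).astype(float)
        X[rng.random((50, 200)) < 0.08] = np.nan
        X[:, :5] = 0.0  # planted monomorphic
        X[: 40, 5] = np.nan  # planted low call rate
        geno = make_genotypes(X)
        out, _ = qc_genotypes(geno, maf_min=0.05, call_rate_min=0.9)

        survivors = []
        for j in range(200):
            col = X[:, j]
            obs = col[~np.isnan(col)]
            cr = len(obs) / 50
            f = obs.mean() / 2 if len(obs) else 0.0
            if cr > 0.9 and min(f, 1 - f) > 0.05:
                survivors.append(f"snp{j}")
        assert out.snp_ids == survivors


class TestGRM:
    def test_direct_formula_evaluation(self):
        X = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
        G = compute_grm(make_genotypes(X)).values
        f = X.mean(axis=0) / 2
        Z = X - 2 * f
        expected = Z @ Z.T / (2 * np.sum(f * (1 - f)))
        np.testing.assert_allclose(G, expected, atol=1e-12)

    def test_identical_individuals_indistinguishable(self):
        X = np.array([[0.0, 2.0, 1.0], [0.0, 2.0, 1.0], [2.0, 0.0, 1.0]])
        G = compute_grm(make_genotypes(X)).values
        assert G[0, 0] == pytest.approx(G[0, 1])
        assert G[0, 0] == pytest.approx(G[1, 1])

    def test_monomorphic_rejected(self):
        with pytest.raises(InputError):
            compute_grm(make_genotypes([[0, 1], [0, 2]]))

    def test_hwe_mean_diagonal_near_one(self):
        cfg = SimulationConfig(n_individuals=400, n_snps=5000,
                               taxa_h2=[0.0], taxa_prevalence=[1.0], seed=5)
        G = compute_grm(simulate_genotypes(cfg)).values
        assert 0.9 < np.diag(G).mean() < 1.1

    def test_invariant_to_snp_order_and_sample_permutation(self):
        rng = np.random.default_rng(3)
        X = rng.binomial(2, rng.uniform(0.1, 0.5, 40), size=(15, 40)).astype(float)
        geno = make_genotypes(X)
        G = compute_grm(geno).values
        # SNP column shuffle leaves G unchanged
        perm_snps = rng.permutation(40)
        G_shuf = compute_grm(make_genotypes(X[:, perm_snps])).values
        np.testing.assert_allclose(G, G_shuf, atol=1e-12)
        # sample permutation permutes G the same way
        perm = rng.permutation(15)
        G_perm = compute_grm(make_genotypes(X[perm])).values
        np.testing.assert_allclose(G_perm, G[np.ix_(perm, perm)], atol=1e-12)

    def test_psd(self, small_cohort):
        small_cohort["G"].check_psd()


class TestMantel:
    @staticmethod
    def _random_kernel(n, seed):
        rng = np.random.default_rng(seed)
        B = rng.standard_normal((n, n + 5))
        K = B @ B.T / (n + 5)
        return RelationshipMatrix(K, [f"s{i}" for i in range(n)])

    def test_self_comparison(self):
        A = self._random_kernel(20, 1)
        r, p = mantel_test(A, A, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_anticorrelated_lower_triangle(self):
        A = self._random_kernel(12, 2)
        Bv = -A.values.copy()
        np.fill_diagonal(Bv, np.diag(A.values))
        B = RelationshipMatrix(Bv, A.sample_ids)
        r, _ = mantel_test(A, B, n_perm=99, seed=0)
        assert r == pytest.approx(-1.0)

    def test_statistic_matches_direct_offdiagonal_correlation(self):
        A = self._random_kernel(5, 3)
        B = self._random_kernel(5, 4)
        r, _ = mantel_test(A, B, n_perm=99, seed=0)
        il = np.tril_indices(5, k=-1)
        expected = np.corrcoef(A.values[il], B.values[il])[0, 1]
        assert r == pytest.approx(expected, abs=1e-12)

    def test_mismatched_ids_rejected(self):
        A = self._random_kernel(5, 3)
        B = self._random_kernel(5, 4)
        B.sample_ids = [f"x{i}" for i in range(5)]
        with pytest.raises(InputError):
            mantel_test(A, B, n_perm=99, seed=0)

    def test_seed_determinism(self):
        A = self._random_kernel(10, 5)
        B = self._random_kernel(10, 6)
        assert mantel_test(A, B, 199, seed=9) == mantel_test(A, B, 199, seed=9)

    def test_null_pvalues_super_uniform(self):
        """Independent kernels: rejection rate at 0.05 stays below 0.08."""
        A = self._random_kernel(25, 100)
        hits = 0
        for i in range(200):
            B = self._random_kernel(25, 1000 + i)
            _, p = mantel_test(A, B, n_perm=99, seed=i)
            hits += p < 0.05
        assert hits / 200 <= 0.08
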