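"""Mixed-model GWAS (P3D) and Benjamini-Hochberg adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from holoherit import InputError, bh_adjust, compute_grm, run_mm_gwas
from holoherit.simulate import SimulationConfig, simulate_genotypes


def textbook_bh(p):
    """Step-up BH written directly from the definition (test oracle)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running_min = min(running_min, p[idx] * m / rank)
        adj[idx] = running_min
    return adj


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_textbook_example(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(got, textbook_bh([0.01, 0.02, 0.03, 0.04]))

    def test_matches_textbook_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = rng.random(rng.integers(1, 60))
            np.testing.assert_allclose(bh_adjust(p), textbook_bh(p), atol=1e-12)

    def test_reorder_equivariance(self):
        rng = np.random.default_rng(7)
        p = rng.random(25)
        perm = rng.permutation(25)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), atol=1e-12)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(8)
        p = rng.random(50)
        assert np.all(bh_adjust(p) >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.2])


def _scan_setup(seed, n=300, p=500, r2=0.2, causal=37):
    """Genotypes + one taxon trait with a planted SNP explaining r2 variance."""
    cfg = SimulationConfig(n_individuals=n, n_snps=p, taxa_h2=[0.0],
                           taxa_prevalence=[1.0], seed=seed)
    geno = simulate_genotypes(cfg)
    G = compute_grm(geno)
    rng = np.random.default_rng(seed + 1)
    s = geno.dosage[:, causal] - 1.0
    s = (s - s.mean()) / s.std()
    y = np.sqrt(r2) * s + np.sqrt(1 - r2) * rng.standard_normal(n)
    vals = pd.DataFrame({"taxonA": y}, index=geno.sample_ids)
    return geno, G, vals


class TestScan:
    def test_planted_snp_is_top_hit(self):
        geno, G, vals = _scan_setup(seed=0)
        table = run_mm_gwas(vals, geno, G)
        top = table.iloc[0]
        assert top["snp_id"] == geno.snp_ids[37]
        assert top["fdr"] < 0.01 and top["tier"] == "significant"

    def test_fdr_at_least_p_and_tiers_consistent(self):
        geno, G, vals = _scan_setup(seed=1)
        table = run_mm_gwas(vals, geno, G)
        assert (table["fdr"] >= table["p"] - 1e-15).all()
        sig = table["tier"] == "significant"
        assert (table.loc[sig, "fdr"] < 0.01).all()
        assert (table.loc[~sig, "fdr"] >= 0.01).all()

    def test_allele_flip_equivariance(self):
        """Flipping a SNP's allele labels flips beta; p is unchanged."""
        geno, G, vals = _scan_setup(seed=2)
        t1 = run_mm_gwas(vals, geno, G).set_index("snp_id")
        flipped = geno.dosage.copy()
        flipped[:, 10] = 2.0 - flipped[:, 10]
        from conftest import make_genotypes

        geno2 = make_genotypes(flipped, sample_ids=list(geno.sample_ids),
                               snp_ids=list(geno.snp_ids))
        t2 = run_mm_gwas(vals, geno2, G).set_index("snp_id")
        snp = geno.snp_ids[10]
        assert t2.loc[snp, "beta"] == pytest.approx(-t1.loc[snp, "beta"], rel=1e-9)
        assert t2.loc[snp, "p"] == pytest.approx(t1.loc[snp, "p"], rel=1e-9)

    def test_monomorphic_snp_skipped_and_counted(self):
        geno, G, vals = _scan_setup(seed=3)
        dosage = geno.dosage.copy()
        dosage[:, 0] = 2.0
        from conftest import make_genotypes

        geno2 = make_genotypes(dosage, sample_ids=list(geno.sample_ids),
                               snp_ids=list(geno.snp_ids))
        table = run_mm_gwas(vals, geno2, G)
        assert geno.snp_ids[0] not in set(table["snp_id"])
        assert table.attrs["n_monomorphic_skipped"] == 1

    def test_null_pvalues_uniform(self):
        """Phenotype shuffled against genotypes gives uniform p-values."""
        geno, G, vals = _scan_setup(seed=4, r2=0.2)
        rng = np.random.default_rng(99)
        shuffled = vals.copy()
        shuffled["taxonA"] = rng.permutation(shuffled["taxonA"].to_numpy())
        table = run_mm_gwas(shuffled, geno, G)
        ks = stats.kstest(table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_p3d_and_exact_agree_on_top_hits(self):
        """Small n: P3D and exact per-SNP REML rank the top-10 identically
        in at least 90% of seeded replicates (10 planted SNPs with graded
        effects, so the top ranks are meaningful rather than tied nulls)."""
        agree = 0
        n_reps = 10
        for rep in range(n_reps):
            cfg = SimulationConfig(n_individuals=90, n_snps=60, taxa_h2=[0.0],
                                   taxa_prevalence=[1.0], seed=300 + rep)
            geno = simulate_genotypes(cfg)
            G = compute_grm(geno)
            rng = np.random.default_rng(400 + rep)
            y = rng.standard_normal(90) * 0.6
            for k, b in enumerate(np.linspace(1.0, 0.3, 10)):
                s = geno.dosage[:, k] - 1.0
                y += b * (s - s.mean()) / s.std()
            vals = pd.DataFrame({"taxonA": y}, index=geno.sample_ids)
            approx = run_mm_gwas(vals, geno, G)
            exact = run_mm_gwas(vals, geno, G, exact=True)
            agree += list(approx.head(10)["snp_id"]) == list(exact.head(10)["snp_id"])
        assert agree / n_reps >= 0.9

    def test_misaligned_samples_rejected(self):
        geno, G, vals = _scan_setup(seed=5)
        with pytest.raises(InputError):
            run_mm_gwas(vals.iloc[::-1], geno, G)
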