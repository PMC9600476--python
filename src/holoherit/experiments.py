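"""Replicated simulation experiments: parameter recovery and calibration.

These drive the package end to end on synthetic cohorts with planted truth
and summarize how well the estimators recover it.  They are shared by the
analysis scripts and the validation suite; problem sizes default to the
study-scale conditions (n = 400 animals, 2,000 SNPs, 60 taxa with planted
h2 in {0, 0.3, 0.6}; q = 100 taxa at m2 = 0.30).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genomics import compute_grm
from .gwas import run_mm_gwas
from .pipeline import (
    HERITABILITY_COVARIATES,
    PhenotypeTable,
    estimate_taxon_heritability,
    estimate_trait_microbiability,
)
from .simulate import (
    FILLER_TAXON,
    SimulationConfig,
    TraitSpec,
    simulate_cohort,
    simulate_genotypes,
)

__all__ = [
    "heritability_recovery",
    "microbiability_recovery",
    "gwas_planted_snp_recovery",
    "gwas_null_uniformity",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def heritability_recovery(
    seed: int,
    n_reps: int = 30,
    n_individuals: int = 400,
    n_snps: int = 2000,
    h2_levels: tuple[float, ...] = (0.0, 0.3, 0.6),
    taxa_per_level: int = 20,
) -> pd.DataFrame:
    """Mean h2 estimate and heritable-call rate per planted level.

    Each replicate simulates a full cohort, estimates per-taxon h2 through
    the standard two-stage model (log10, covariate adjustment, animal
    model), and pools estimates by the planted value.  Returns a frame
    indexed by planted h2 with columns mean_estimate, bias, heritable_rate,
    n_estimates.
    """
    h2 = [h for lv in h2_levels for h in [lv] * taxa_per_level]
    est: dict[float, list[float]] = {lv: [] for lv in h2_levels}
    calls: dict[float, list[bool]] = {lv: [] for lv in h2_levels}
    for rep_seed in _child_seeds(seed, n_reps):
        cfg = SimulationConfig(
            n_individuals=n_individuals,
            n_snps=n_snps,
            taxa_h2=h2,
            taxa_prevalence=[1.0] * len(h2),
            seed=rep_seed,
        )
        geno, taxa, phenos, truth = simulate_cohort(cfg)
        G = compute_grm(geno)
        cov = phenos[list(HERITABILITY_COVARIATES)]
        results, _ = estimate_taxon_heritability(taxa, G, cov)
        for r in results:
            if r.taxon_id in truth.taxa_h2:
                lv = truth.taxa_h2[r.taxon_id]
                est[lv].append(r.fit.ratio)
                calls[lv].append(r.status == "heritable")
    rows = {
        lv: {
            "mean_estimate": float(np.mean(est[lv])),
            "bias": float(np.mean(est[lv]) - lv),
            "heritable_rate": float(np.mean(calls[lv])),
            "n_estimates": len(est[lv]),
        }
        for lv in h2_levels
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "planted_h2"
    return out


def microbiability_recovery(
    seed: int,
    n_reps: int = 20,
    n_individuals: int = 400,
    n_taxa: int = 100,
    m2: float = 0.30,
) -> pd.DataFrame:
    """Mean m2 estimate for a planted trait and a null (m2 = 0) trait.

    The kernel covers the whole planted community (prevalence 1), matching
    the generating model; the trait model carries the standard covariates.
    """
    vals: list[float] = []
    nulls: list[float] = []
    for rep_seed in _child_seeds(seed, n_reps):
        cfg = SimulationConfig(
            n_individuals=n_individuals,
            n_snps=400,  # genotypes only shape the taxa; a light panel suffices
            taxa_h2=[0.0] * n_taxa,
            taxa_prevalence=[1.0] * n_taxa,
            trait_specs=[TraitSpec("planted", m2), TraitSpec("null", 0.0)],
            seed=rep_seed,
        )
        _, taxa, phenos, _ = simulate_cohort(cfg)
        planted = [t for t in taxa.taxon_ids if t != FILLER_TAXON]
        pt = PhenotypeTable(phenos)
        vals.append(estimate_trait_microbiability(pt, taxa, planted, "planted").m2)
        nulls.append(estimate_trait_microbiability(pt, taxa, planted, "null").m2)
    return pd.DataFrame(
        {
            "planted_m2": [m2, 0.0],
            "mean_estimate": [float(np.mean(vals)), float(np.mean(nulls))],
            "n_reps": [n_reps, n_reps],
        },
        index=["planted", "null"],
    )


def _planted_snp_cohort(rep_seed: int, n: int, p: int, r2: float, causal_idx: int):
    cfg = SimulationConfig(
        n_individuals=n, n_snps=p, taxa_h2=[0.0], taxa_prevalence=[1.0], seed=rep_seed
    )
    geno = simulate_genotypes(cfg)
    G = compute_grm(geno)
    rng = np.random.default_rng(rep_seed ^ 0x5EED)
    s = geno.dosage[:, causal_idx] - 1.0
    s = (s - s.mean()) / s.std()
    y = np.sqrt(r2) * s + np.sqrt(1.0 - r2) * rng.standard_normal(n)
    vals = pd.DataFrame({"taxon": y}, index=geno.sample_ids)
    return geno, G, vals


def gwas_planted_snp_recovery(
    seed: int,
    n_reps: int = 20,
    n_individuals: int = 400,
    n_snps: int = 2000,
    r2: float = 0.20,
) -> float:
    """Fraction of replicates where the planted SNP is the top hit at FDR < 0.01."""
    hits = 0
    causal = 123
    for rep_seed in _child_seeds(seed, n_reps):
        geno, G, vals = _planted_snp_cohort(rep_seed, n_individuals, n_snps, r2, causal)
        table = run_mm_gwas(vals, geno, G)
        top = table.iloc[0]
        hits += (top["snp_id"] == geno.snp_ids[causal]) and (top["fdr"] < 0.01)
    return hits / n_reps


def gwas_null_uniformity(
    seed: int, n_individuals: int = 400, n_snps: int = 2000
) -> float:
    """KS-test p-value for uniformity of scan p-values under a permuted null."""
    geno, G, vals = _planted_snp_cohort(seed, n_individuals, n_snps, 0.2, 123)
    rng = np.random.default_rng(seed + 1)
    vals = vals.copy()
    vals["taxon"] = rng.permutation(vals["taxon"].to_numpy())
    table = run_mm_gwas(vals, geno, G)
    return float(stats.kstest(table["p"], "uniform").pvalue)
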