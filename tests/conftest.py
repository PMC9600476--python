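import numpy as np
import pandas as pd
import pytest

from holoherit import SimulationConfig, compute_grm, simulate_cohort
from holoherit.genomics import GenotypeMatrix, RelationshipMatrix
from holoherit.simulate import TraitSpec


def make_genotypes(dosage, sample_ids=None, snp_ids=None):
    dosage = np.asarray(dosage, dtype=float)
    n, p = dosage.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    snp_ids = snp_ids or [f"snp{j}" for j in range(p)]
    vmap = pd.DataFrame({"snp_id": snp_ids, "chrom": 1, "bp": range(1, p + 1)})
    return GenotypeMatrix(sample_ids, snp_ids, dosage, vmap)


def family_kernel(n_families=2, family_size=4, within=0.5):
    """Block kernel: 1 on the diagonal, `within` inside families, 0 across."""
    n = n_families * family_size
    K = np.zeros((n, n))
    for f in range(n_families):
        s = slice(f * family_size, (f + 1) * family_size)
        K[s, s] = within
    np.fill_diagonal(K, 1.0)
    return RelationshipMatrix(K, [f"s{i}" for i in range(n)], kind="genomic")


@pytest.fixture(scope="session")
def small_cohort():
    """One modest simulated cohort shared by read-only tests."""
    cfg = SimulationConfig(
        n_individuals=120,
        n_snps=400,
        taxa_h2=[0.0] * 5 + [0.5] * 5,
        taxa_prevalence=[1.0] * 10,
        trait_specs=[
            TraitSpec("MY", 0.3, mean=30, sd=5),
            TraitSpec("MP", 0.3, mean=0.032, sd=0.002),
            TraitSpec("MF", 0.3, mean=0.040, sd=0.004),
            TraitSpec("acetate", 0.3, mean=60, sd=8),
            TraitSpec("total_vfa", 0.3, mean=96, sd=11),
        ],
        seed=42,
    )
    geno, taxa, phenos, truth = simulate_cohort(cfg)
    G = compute_grm(geno)
    return {"config": cfg, "geno": geno, "taxa": taxa, "phenos": phenos, "truth": truth, "G": G}
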