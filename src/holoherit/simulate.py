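"""Synthetic cohort generator with known ground truth.

Emulates the study design the pipeline targets: a mid-lactation dairy-cow
cohort with chip genotypes, a species-level rumen taxa table, and
lactation/VFA phenotypes.  Every quantity the downstream estimators try to
recover — per-taxon heritability, per-trait microbiability, the underlying
effect vectors — is planted with a known value and returned in a
:class:`SimulationTruth`, so parameter-recovery and null-calibration tests
need no external data.

Generative model
----------------
* Genotypes: biallelic SNPs in Hardy-Weinberg equilibrium, dosage
  ~ Binomial(2, f) with f uniform on ``maf_range``; variants assigned
  round-robin to the 29 bovine autosomes.
* Taxa: latent log-abundance x_j = mu_j + a_j + eps_j with
  a_j ~ N(0, sa2 G) drawn through a symmetric eigen square-root of the
  genomic relationship matrix, eps_j ~ N(0, se2 I), sa2/(sa2+se2) equal to
  the planted h2.  Zero inflation truncates the smallest latent values so
  the realized prevalence is exact; rows are closed to proportions by a
  filler "remainder" taxon so the planted taxa columns keep their exact
  values.
* Phenotypes: trait = covariate effects + O w + e with O the standardized
  log-abundance matrix of the detected planted taxa, w_j ~ N(0, sm2/q), and
  sm2/(sm2+se2) equal to the planted m2.  Protein/fat yields and
  energy-corrected milk are derived deterministically from the base traits.

Zero-inflated taxa are meant for filter/classification tests; truncation
biases the realized heritability, so recovery checks use prevalence 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import stage_rng, stage_seed
from .genomics import GenotypeMatrix, InputError, compute_grm
from .microbiome import DETECTION_PREVALENCE, TaxaTable, standardize_log_abundance

__all__ = [
    "TraitSpec",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_genotypes",
    "simulate_taxa_abundances",
    "simulate_phenotypes",
    "simulate_cohort",
    "default_trait_specs",
    "FILLER_TAXON",
]

FILLER_TAXON = "remainder"
N_AUTOSOMES = 29

#: base traits simulated directly; yields and ECM are derived
_BASE_TRAIT_SCALES = {
    # name: (mean, sd) on the observed scale
    "MY": (30.0, 5.0),  # kg/d
    "MP": (0.032, 0.002),  # protein content, kg/kg
    "MF": (0.040, 0.004),  # fat content, kg/kg
    "acetate": (60.0, 8.0),  # mM
    "propionate": (20.0, 4.0),
    "butyrate": (12.0, 2.0),
    "isobutyrate": (1.0, 0.2),
    "valerate": (1.6, 0.3),
    "isovalerate": (1.3, 0.25),
    "total_vfa": (96.0, 11.0),
}

DERIVED_TRAITS = ("MPY", "MFY", "ECM")
COVARIATES = ("subcohort", "parity", "age", "days_in_milk", "ph")


@dataclass
class TraitSpec:
    """One simulated base trait: planted microbiability and covariate effects.

    ``covariate_effects`` are on the standardized-covariate scale (one unit
    = one SD of the covariate, or the second subcohort level).
    """

    name: str
    m2: float
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {
            "subcohort": 0.4,
            "parity": 0.15,
            "age": 0.05,
            "days_in_milk": -0.10,
        }
    )
    mean: float = 0.0
    sd: float = 1.0


def default_trait_specs(m2: float = 0.30) -> list[TraitSpec]:
    return [
        TraitSpec(name, m2, mean=mu, sd=sd)
        for name, (mu, sd) in _BASE_TRAIT_SCALES.items()
    ]


def _default_h2() -> list[float]:
    return [0.0] * 20 + [0.3] * 20 + [0.6] * 20


@dataclass
class SimulationConfig:
    n_individuals: int = 400
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    taxa_h2: list[float] = field(default_factory=_default_h2)
    taxa_prevalence: list[float] = field(default_factory=lambda: [1.0] * 60)
    trait_specs: list[TraitSpec] = field(default_factory=default_trait_specs)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InputError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if len(self.taxa_h2) != len(self.taxa_prevalence):
            raise InputError("taxa_h2 and taxa_prevalence must have equal length")
        if any(not (0.0 <= h < 1.0) for h in self.taxa_h2):
            raise InputError("taxa_h2 entries must be in [0, 1)")
        if any(not (0.0 < p <= 1.0) for p in self.taxa_prevalence):
            raise InputError("taxa_prevalence entries must be in (0, 1]")
        for ts in self.trait_specs:
            if not (0.0 <= ts.m2 < 1.0):
                raise InputError(f"trait {ts.name}: m2 must be in [0, 1)")


@dataclass
class SimulationTruth:
    """Planted parameters and effect vectors — the recovery-test oracle."""

    seeds: dict[str, int] = field(default_factory=dict)
    taxa_h2: dict[str, float] = field(default_factory=dict)
    genetic_values: pd.DataFrame | None = None  # n x t, the a_j vectors
    trait_m2: dict[str, float] = field(default_factory=dict)
    microbial_effects: pd.DataFrame | None = None  # q x traits, the w vectors
    covariate_coefficients: dict[str, dict[str, float]] = field(default_factory=dict)

    def merge(self, other: "SimulationTruth") -> "SimulationTruth":
        out = SimulationTruth(
            seeds={**self.seeds, **other.seeds},
            taxa_h2={**self.taxa_h2, **other.taxa_h2},
            genetic_values=self.genetic_values if other.genetic_values is None else other.genetic_values,
            trait_m2={**self.trait_m2, **other.trait_m2},
            microbial_effects=self.microbial_effects if other.microbial_effects is None else other.microbial_effects,
            covariate_coefficients={**self.covariate_coefficients, **other.covariate_coefficients},
        )
        return out


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """HWE biallelic dosages with a round-robin autosome map."""
    n, p = config.n_individuals, config.n_snps
    if n < 2 or p < 1:
        raise InputError("need n_individuals >= 2 and n_snps >= 1")
    rng = stage_rng(config.seed, "genotypes")
    lo, hi = config.maf_range
    f = rng.uniform(lo, hi, size=p)
    dosage = rng.binomial(2, f, size=(n, p)).astype(float)
    sample_ids = [f"cow{i + 1:04d}" for i in range(n)]
    snp_ids = [f"snp{j + 1:06d}" for j in range(p)]
    chrom = [(j % N_AUTOSOMES) + 1 for j in range(p)]
    bp = [50_000 * (j // N_AUTOSOMES + 1) for j in range(p)]
    vmap = pd.DataFrame({"snp_id": snp_ids, "chrom": chrom, "bp": bp})
    return GenotypeMatrix(sample_ids, snp_ids, dosage, vmap)


def _kernel_sqrt(G: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Symmetric eigen square-root; eigenvalues clipped at zero."""
    w, V = np.linalg.eigh((G + G.T) / 2.0)
    scale = max(1.0, float(abs(w).max()))
    if w.min() < -tol * scale:
        raise InputError(f"kernel not PSD (min eig {w.min():.3g})")
    return V @ (np.sqrt(np.clip(w, 0.0, None))[:, None] * V.T)


def simulate_taxa_abundances(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> tuple[TaxaTable, SimulationTruth]:
    """Taxa proportions with planted per-taxon heritability and prevalence."""
    n = genotypes.n_samples
    t = len(config.taxa_h2)
    rng = stage_rng(config.seed, "taxa")

    # GRM from the polymorphic SNPs (tiny simulations can fix an allele)
    f = genotypes.allele_freq()
    poly = (f > 0) & (f < 1)
    if not poly.any():
        raise InputError("all simulated SNPs monomorphic; increase n or MAF")
    G = compute_grm(genotypes.subset_snps(poly)).values
    A = _kernel_sqrt(G)

    # latent means keep the expected summed abundance well below 1 so the
    # filler taxon can absorb the balance without renormalizing the planted
    # columns; the per-taxon cap guards the lognormal tail when t is small
    mu = np.log(min(0.3 / t, 0.02)) - 0.5

    abundance = np.empty((n, t))
    genetic = np.empty((n, t))
    for j, (h2, prev) in enumerate(zip(config.taxa_h2, config.taxa_prevalence)):
        a = np.sqrt(h2) * (A @ rng.standard_normal(n))
        eps = np.sqrt(1.0 - h2) * rng.standard_normal(n)
        x = mu + a + eps
        raw = np.exp(x)
        n_zero = int(round(n * (1.0 - prev)))
        if n_zero > 0:
            raw[np.argsort(raw)[:n_zero]] = 0.0
        abundance[:, j] = raw
        genetic[:, j] = a

    total = abundance.sum(axis=1)
    over = total >= 1.0
    if over.any():
        warnings.warn(
            f"{int(over.sum())} rows exceeded total abundance 1; rescaled to 0.99",
            stacklevel=2,
        )
        abundance[over] *= (0.99 / total[over])[:, None]
        total = abundance.sum(axis=1)

    taxon_ids = [f"taxon{j + 1:03d}" for j in range(t)]
    df = pd.DataFrame(abundance, index=genotypes.sample_ids, columns=taxon_ids)
    df[FILLER_TAXON] = 1.0 - total
    truth = SimulationTruth(
        seeds={"taxa": stage_seed(config.seed, "taxa")},
        taxa_h2=dict(zip(taxon_ids, config.taxa_h2)),
        genetic_values=pd.DataFrame(genetic, index=genotypes.sample_ids, columns=taxon_ids),
    )
    return TaxaTable(df), truth


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def simulate_phenotypes(
    taxa: TaxaTable, config: SimulationConfig
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Covariates plus traits carrying a planted microbial variance fraction.

    Returns a phenotype/covariate DataFrame indexed by sample id with the
    base traits, the derived yields (MPY, MFY) and energy-corrected milk.
    """
    from .pipeline import compute_ecm  # deferred: pipeline imports nothing from here

    rng = stage_rng(config.seed, "phenotypes")
    n = taxa.n_samples

    cov = pd.DataFrame(index=taxa.abundance.index)
    cov["subcohort"] = np.where(rng.random(n) < 0.72, "c2016", "c2019")
    cov["parity"] = rng.choice([1, 2, 3, 4, 5], size=n, p=[0.25, 0.30, 0.20, 0.15, 0.10])
    cov["age"] = cov["parity"] + rng.uniform(1.5, 3.0, size=n)  # years
    cov["days_in_milk"] = rng.integers(125, 186, size=n)
    cov["ph"] = rng.uniform(5.5, 7.0, size=n)

    planted = [c for c in taxa.taxon_ids if c != FILLER_TAXON]
    prev = taxa.prevalence()
    detected = [c for c in planted if prev[c] >= DETECTION_PREVALENCE]
    if len(detected) < 2:
        raise InputError("need at least 2 detected taxa to plant a microbial effect")
    O = standardize_log_abundance(taxa, detected).to_numpy()
    q = O.shape[1]

    cov_std = {
        "subcohort": (cov["subcohort"] == "c2019").to_numpy(float),
        "parity": _standardize(cov["parity"].to_numpy(float)),
        "age": _standardize(cov["age"].to_numpy(float)),
        "days_in_milk": _standardize(cov["days_in_milk"].to_numpy(float)),
        "ph": _standardize(cov["ph"].to_numpy(float)),
    }

    traits = pd.DataFrame(index=taxa.abundance.index)
    w_all = {}
    coefs = {}
    for ts in config.trait_specs:
        w = rng.normal(0.0, np.sqrt(ts.m2 / q), size=q)
        g = O @ w
        e = rng.normal(0.0, np.sqrt(1.0 - ts.m2), size=n)
        fixed = sum(
            b * cov_std[name] for name, b in ts.covariate_effects.items()
        )
        y_std = (fixed if isinstance(fixed, np.ndarray) else 0.0) + g + e
        traits[ts.name] = ts.mean + ts.sd * y_std
        w_all[ts.name] = w
        coefs[ts.name] = dict(ts.covariate_effects)

    if {"MY", "MP", "MF"} <= set(traits.columns):
        traits["MPY"] = traits["MP"] * traits["MY"]
        traits["MFY"] = traits["MF"] * traits["MY"]
        traits["ECM"] = compute_ecm(
            traits["MY"].to_numpy(),
            traits["MFY"].to_numpy(),
            traits["MPY"].to_numpy(),
        )

    phenos = pd.concat([cov, traits], axis=1)
    truth = SimulationTruth(
        seeds={"phenotypes": stage_seed(config.seed, "phenotypes")},
        trait_m2={ts.name: ts.m2 for ts in config.trait_specs},
        microbial_effects=pd.DataFrame(w_all, index=detected),
        covariate_coefficients=coefs,
    )
    return phenos, truth


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, TaxaTable, pd.DataFrame, SimulationTruth]:
    """Genotypes, taxa table, phenotypes and merged truth for one cohort."""
    geno = simulate_genotypes(config)
    taxa, truth_t = simulate_taxa_abundances(geno, config)
    phenos, truth_p = simulate_phenotypes(taxa, config)
    truth = truth_t.merge(truth_p)
    truth.seeds["root"] = config.seed
    return geno, taxa, phenos, truth
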