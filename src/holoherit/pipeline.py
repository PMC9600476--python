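"""Headline analyses: per-taxon heritability, subcommunity microbiability,
mean microbiability, and derived lactation traits.

Heritability is estimated in two stages, as is conventional for microbial
phenotypes: log10-transformed abundances are first adjusted for fixed
effects (subcohort, parity, age, days-in-milk, ruminal pH) by OLS, and the
residuals enter an animal model against the genomic kernel G with an
intercept-only fixed part.  Microbiability is a single-stage mixed model:
the trait carries its covariates (subcohort, parity, age, days-in-milk —
no pH) inside the model, with the microbial kernel M built per
subcommunity.  The mean microbiability beta2 = m2 / o spreads a
subcommunity's total contribution uniformly over its o taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .genomics import InputError, RelationshipMatrix
from .microbiome import TaxaTable, build_mrm
from .varcomp import (
    RemlWorkspace,
    VarCompFit,
    adjust_fixed_effects,
    build_design,
    classify_heritable,
)

__all__ = [
    "PhenotypeTable",
    "HeritabilityResult",
    "MicrobiabilityResult",
    "compute_ecm",
    "adjusted_log_abundance",
    "estimate_taxon_heritability",
    "estimate_microbiability",
    "estimate_trait_microbiability",
    "mean_microbiability",
    "percent_round",
    "MILK_TRAITS",
    "VFA_TRAITS",
    "HERITABILITY_COVARIATES",
    "MICROBIABILITY_COVARIATES",
]

logger = logging.getLogger(__name__)

MILK_TRAITS = ("MY", "MP", "MPY", "MF", "MFY", "ECM")
VFA_TRAITS = (
    "acetate",
    "propionate",
    "butyrate",
    "isobutyrate",
    "valerate",
    "isovalerate",
    "total_vfa",
)
HERITABILITY_COVARIATES = ("subcohort", "parity", "age", "days_in_milk", "ph")
MICROBIABILITY_COVARIATES = ("subcohort", "parity", "age", "days_in_milk")

# ECM(kg/d) from milk, fat and protein yields
_ECM_MY, _ECM_MFY, _ECM_MPY = 0.3246, 13.86, 7.04


@dataclass
class PhenotypeTable:
    """Traits and covariates, one row per animal.

    Checks the definitional identities MPY = MP * MY and MFY = MF * MY
    whenever all three columns are present.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if not df.index.is_unique:
            raise InputError("sample ids must be unique")
        for prod, a, b in (("MPY", "MP", "MY"), ("MFY", "MF", "MY")):
            if {prod, a, b} <= set(df.columns):
                if not np.allclose(df[prod], df[a] * df[b], atol=1e-6):
                    raise InputError(f"{prod} != {a} * {b}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def covariates(self, names: tuple[str, ...]) -> pd.DataFrame:
        missing = [c for c in names if c not in self.data.columns]
        if missing:
            raise InputError(f"missing covariates: {missing}")
        return self.data[list(names)]


@dataclass
class HeritabilityResult:
    taxon_id: str
    fit: VarCompFit
    status: str  # "heritable" | "nonheritable"
    category: str  # "high" | "moderate" | "low" | ""
    log10_pseudocount: float


@dataclass
class MicrobiabilityResult:
    trait: str
    group: str  # "heritable" | "nonheritable"
    m2: float
    m2_se: float
    o: int  # subcommunity size entering the kernel
    beta2: float  # mean microbiability, m2 / o


def compute_ecm(my, mfy, mpy):
    """Energy-corrected milk (kg/d) from milk, fat and protein yields."""
    my, mfy, mpy = (np.asarray(v, dtype=float) for v in (my, mfy, mpy))
    if (my < 0).any() or (mfy < 0).any() or (mpy < 0).any():
        raise InputError("yields must be non-negative")
    out = _ECM_MY * my + _ECM_MFY * mfy + _ECM_MPY * mpy
    return float(out) if out.ndim == 0 else out


def _check_alignment(ids_a: list[str], ids_b: list[str], what: str) -> None:
    if ids_a != ids_b:
        unmatched = sorted(set(ids_a) ^ set(ids_b))
        raise InputError(
            f"sample misalignment between taxa and {what}: "
            f"{unmatched[:5] or 'same ids, different order'}"
        )


def adjusted_log_abundance(
    taxa: TaxaTable, covariates: pd.DataFrame | None
) -> tuple[pd.DataFrame, float]:
    """log10(proportion + delta) abundances, OLS-adjusted for fixed effects.

    delta is half the smallest nonzero proportion in the whole table (a
    standard microbiome pseudocount choice); the same delta is used for
    every taxon and returned alongside the adjusted values.
    """
    if covariates is not None:
        _check_alignment(taxa.sample_ids, list(covariates.index), "covariates")
    vals = taxa.abundance.to_numpy(dtype=float)
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        raise InputError("taxa table is all zeros")
    delta = float(nonzero.min()) / 2.0
    logvals = np.log10(vals + delta)
    adj = np.column_stack(
        [adjust_fixed_effects(logvals[:, j], covariates) for j in range(vals.shape[1])]
    )
    return (
        pd.DataFrame(adj, index=taxa.abundance.index, columns=taxa.abundance.columns),
        delta,
    )


def estimate_taxon_heritability(
    taxa: TaxaTable,
    G: RelationshipMatrix,
    covariates: pd.DataFrame | None,
) -> tuple[list[HeritabilityResult], dict[str, list[str]]]:
    """Per-taxon h2 against the genomic kernel, with heritable classification.

    Abundances are log10(proportion + delta) with delta = half the smallest
    nonzero proportion in the table, adjusted for fixed effects by OLS, then
    fitted with an intercept-only animal model.  Returns one result per
    taxon and the heritable/nonheritable id partition.
    """
    _check_alignment(taxa.sample_ids, list(G.sample_ids), "G")
    adj, delta = adjusted_log_abundance(taxa, covariates)

    ws = RemlWorkspace(G)  # intercept-only; shared across taxa
    results: list[HeritabilityResult] = []
    partition: dict[str, list[str]] = {"heritable": [], "nonheritable": []}
    for taxon in taxa.taxon_ids:
        fit = ws.fit(adj[taxon].to_numpy())
        if fit.converged:
            status, category = classify_heritable(fit)
        else:  # pragma: no cover - bounded Brent essentially always converges
            logger.warning("taxon %s: REML did not converge; not classified", taxon)
            status, category = "nonheritable", ""
        results.append(HeritabilityResult(taxon, fit, status, category, delta))
        partition[status].append(taxon)
    return results, partition


def estimate_trait_microbiability(
    phenos: PhenotypeTable,
    taxa: TaxaTable,
    taxa_ids: list[str],
    trait: str,
    group: str = "community",
) -> MicrobiabilityResult:
    """m2 of one trait against the kernel of one taxon subset.

    The building block of :func:`estimate_microbiability`; also useful on
    its own, e.g. for the whole detected community at once.
    """
    _check_alignment(taxa.sample_ids, phenos.sample_ids, "phenotypes")
    if trait not in phenos.data.columns:
        raise InputError(f"trait {trait!r} absent")
    y = phenos.data[trait].to_numpy(dtype=float)
    if np.var(y) == 0 or np.isnan(y).any():
        raise InputError(f"trait {trait!r} constant or missing")
    M = build_mrm(taxa, list(taxa_ids))
    X = build_design(phenos.covariates(MICROBIABILITY_COVARIATES))
    fit = RemlWorkspace(M, X).fit(y)
    o = _kernel_q(taxa, list(taxa_ids))
    return MicrobiabilityResult(
        trait=trait,
        group=group,
        m2=fit.ratio,
        m2_se=fit.ratio_se,
        o=o,
        beta2=mean_microbiability(fit.ratio, o),
    )


def estimate_microbiability(
    phenos: PhenotypeTable,
    taxa: TaxaTable,
    heritable_ids: list[str],
    traits: list[str] | None = None,
) -> list[MicrobiabilityResult]:
    """m2 and beta2 per trait for the heritable and nonheritable subcommunities.

    Each subcommunity gets its own kernel M rebuilt from its taxa; the trait
    model carries subcohort, parity, age and days-in-milk as fixed effects.
    A trait that is absent or degenerate is reported in the log and skipped;
    other traits proceed.
    """
    _check_alignment(taxa.sample_ids, phenos.sample_ids, "phenotypes")
    groups = {
        "heritable": list(heritable_ids),
        "nonheritable": [t for t in taxa.taxon_ids if t not in set(heritable_ids)],
    }
    for name, ids in groups.items():
        if len(ids) < 2:
            raise InputError(f"{name} subcommunity has {len(ids)} taxa; need >= 2")
    if traits is None:
        traits = [t for t in MILK_TRAITS + VFA_TRAITS if t in phenos.data.columns]

    X = build_design(phenos.covariates(MICROBIABILITY_COVARIATES))
    workspaces: dict[str, tuple[RemlWorkspace, int]] = {}
    for name, ids in groups.items():
        M = build_mrm(taxa, ids)
        # o is the number of taxa actually entering the kernel (post drops)
        workspaces[name] = (RemlWorkspace(M, X), _kernel_q(taxa, ids))

    out: list[MicrobiabilityResult] = []
    for trait in traits:
        if trait not in phenos.data.columns:
            logger.warning("trait %s absent; skipped", trait)
            continue
        y = phenos.data[trait].to_numpy(dtype=float)
        if np.var(y) == 0 or np.isnan(y).any():
            logger.warning("trait %s constant or missing; skipped", trait)
            continue
        for name, (ws, o) in workspaces.items():
            fit = ws.fit(y)
            out.append(
                MicrobiabilityResult(
                    trait=trait,
                    group=name,
                    m2=fit.ratio,
                    m2_se=fit.ratio_se,
                    o=o,
                    beta2=mean_microbiability(fit.ratio, o),
                )
            )
    return out


def _kernel_q(taxa: TaxaTable, ids: list[str]) -> int:
    from .microbiome import standardize_log_abundance

    return standardize_log_abundance(taxa, ids).shape[1]


def mean_microbiability(m2: float, o: int) -> float:
    """Mean microbiability beta2 = m2 / o (average single-taxon contribution)."""
    if o == 0:
        raise InputError("o must be positive")
    if not (0.0 <= m2 <= 1.0):
        raise InputError("m2 must be in [0, 1]")
    return m2 / o


def percent_round(ratio: float, ndigits: int = 2) -> float:
    """Ratio -> percent, rounded half-away-from-zero to ``ndigits`` decimals."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(ratio * 100.0)).quantize(q, rounding=ROUND_HALF_UP))
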