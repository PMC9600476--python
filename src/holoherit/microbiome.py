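"""Taxa-table handling: prevalence classification, the microbiota
relationship matrix, and subcommunity summaries.

The microbiota relationship matrix (MRM, ``M``) is built from standardized
log abundances: with ``S_ij`` the relative abundance of taxon j in animal i
plus one,

    O_ij = (log S_ij - mean_i log S_ij) / sd_i(log S_ij),   M = (1/q) O O'

where q is the number of taxa entering the kernel.  Because the column
standardization absorbs any multiplicative constant, M is invariant to the
base of the logarithm; the trace identity trace(M) = n - 1 (sample-sd with
n-1 denominator) is a cheap self-check used throughout the tests.

Prevalence rules follow common core-microbiome practice: a taxon is
*detected* when present (abundance > 0) in at least 20% of animals, *core*
at >= 50%, *noncore* in [20%, 50%).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomics import InputError, RelationshipMatrix

__all__ = [
    "TaxaTable",
    "TaxonClassification",
    "filter_and_classify_taxa",
    "standardize_log_abundance",
    "build_mrm",
    "summarize_subcommunities",
    "DETECTION_PREVALENCE",
    "CORE_PREVALENCE",
]

logger = logging.getLogger(__name__)

DETECTION_PREVALENCE = 0.20
CORE_PREVALENCE = 0.50


@dataclass
class TaxaTable:
    """Individuals x taxa relative abundances (proportions in [0, 1])."""

    abundance: pd.DataFrame  # index = sample ids, columns = taxon ids

    def __post_init__(self) -> None:
        ab = self.abundance
        if not ab.index.is_unique or not ab.columns.is_unique:
            raise InputError("sample and taxon ids must be unique")
        vals = ab.to_numpy(dtype=float)
        if np.isnan(vals).any() or (vals < 0).any() or (vals > 1).any():
            raise InputError("abundances must be proportions in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    def prevalence(self) -> pd.Series:
        """Fraction of samples in which each taxon has abundance > 0."""
        return (self.abundance > 0).mean(axis=0)

    def subset(self, taxon_ids: list[str]) -> "TaxaTable":
        missing = [t for t in taxon_ids if t not in self.abundance.columns]
        if missing:
            raise InputError(f"taxa not in table: {missing[:5]}")
        return TaxaTable(self.abundance[list(taxon_ids)])


@dataclass
class TaxonClassification:
    taxon_id: str
    prevalence: float
    detected: bool
    core_status: str  # "core" | "noncore" | "undetected"


def filter_and_classify_taxa(
    table: TaxaTable,
    detection: float = DETECTION_PREVALENCE,
    core: float = CORE_PREVALENCE,
) -> tuple[TaxaTable, list[TaxonClassification]]:
    """Classify every taxon by prevalence and drop the undetected ones.

    Returns the table restricted to detected taxa (columns in original
    order) and the full classification list (one entry per input taxon).
    """
    if table.abundance.shape[1] == 0:
        raise InputError("empty taxa table")
    prev = table.prevalence()
    classes = []
    for t in table.taxon_ids:
        p = float(prev[t])
        if p >= core:
            status, det = "core", True
        elif p >= detection:
            status, det = "noncore", True
        else:
            status, det = "undetected", False
        classes.append(TaxonClassification(t, p, det, status))
    kept = [c.taxon_id for c in classes if c.detected]
    if not kept:
        raise InputError("no taxa pass the detection threshold")
    return table.subset(kept), classes


def standardize_log_abundance(
    table: TaxaTable, taxa_subset: list[str] | None = None
) -> pd.DataFrame:
    """Column-standardized log(proportion + 1) matrix O (n x q).

    Zero-variance columns are dropped with a warning; the caller reads the
    effective q from the returned frame's width.
    """
    sub = table if taxa_subset is None else table.subset(list(taxa_subset))
    S = sub.abundance.to_numpy(dtype=float) + 1.0
    L = np.log(S)
    mean = L.mean(axis=0)
    sd = L.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(sub.abundance.columns, keep) if not k]
        msg = f"dropping {len(dropped)} zero-variance taxa from O: {dropped[:5]}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    O = (L[:, keep] - mean[keep]) / sd[keep]
    return pd.DataFrame(
        O, index=sub.abundance.index, columns=sub.abundance.columns[keep]
    )


def build_mrm(table: TaxaTable, taxa_subset: list[str] | None = None) -> RelationshipMatrix:
    """Microbiota relationship matrix M = (1/q) O O' over a taxon subset."""
    if table.n_samples < 3:
        raise InputError("need at least 3 samples to build M")
    O = standardize_log_abundance(table, taxa_subset)
    q = O.shape[1]
    if q < 2:
        raise InputError(f"degenerate kernel: only {q} usable taxa after drops")
    Ov = O.to_numpy()
    M = (Ov @ Ov.T) / q
    return RelationshipMatrix(M, list(O.index), kind="microbial")


def summarize_subcommunities(
    table: TaxaTable, heritable_ids: list[str]
) -> pd.DataFrame:
    """Per-group mean prevalence and mean per-animal summed abundance (%).

    Groups ("heritable", "nonheritable") partition the table's taxa.
    Returns a frame indexed by group with columns ``n_taxa``,
    ``mean_presence_pct`` and ``mean_total_abundance_pct``.
    """
    missing = [t for t in heritable_ids if t not in table.abundance.columns]
    if missing:
        raise InputError(f"heritable ids not in table: {missing[:5]}")
    her = set(heritable_ids)
    nonher = [t for t in table.taxon_ids if t not in her]
    prev = table.prevalence()
    rows = {}
    for name, ids in (("heritable", list(heritable_ids)), ("nonheritable", nonher)):
        if ids:
            mean_prev = float(prev[ids].mean()) * 100.0
            total_ab = float(table.abundance[ids].sum(axis=1).mean()) * 100.0
        else:
            mean_prev = np.nan
            total_ab = 0.0
        rows[name] = {
            "n_taxa": len(ids),
            "mean_presence_pct": mean_prev,
            "mean_total_abundance_pct": total_ab,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
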