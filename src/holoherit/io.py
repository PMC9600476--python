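"""Plain-text (TSV) readers and writers for every pipeline table.

All tables are tab-separated with a header row and the individual id in the
first column; missing values are empty fields.  A PLINK-dialect additive
``.raw`` export (FID IID PAT MAT SEX PHENOTYPE then one column per SNP,
``NA`` for missing) is supported for genotypes.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genomics import GenotypeMatrix, InputError, RelationshipMatrix
from .microbiome import TaxaTable, TaxonClassification
from .pipeline import HeritabilityResult, MicrobiabilityResult

__all__ = [
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_plink_raw",
    "read_variant_map",
    "write_variant_map",
    "read_taxa_tsv",
    "write_taxa_tsv",
    "read_phenotypes_tsv",
    "write_phenotypes_tsv",
    "read_relationship_tsv",
    "write_relationship_tsv",
    "write_heritability_tsv",
    "write_microbiability_tsv",
    "write_classification_tsv",
]


def _default_variant_map(snp_ids: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {"snp_id": snp_ids, "chrom": [0] * len(snp_ids), "bp": [0] * len(snp_ids)}
    )


def read_variant_map(path: str | Path) -> pd.DataFrame:
    vmap = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    need = {"snp_id", "chrom", "bp"}
    if not need <= set(vmap.columns):
        raise InputError(f"variant map must have columns {sorted(need)}")
    return vmap


def write_variant_map(vmap: pd.DataFrame, path: str | Path) -> None:
    vmap.to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(
    path: str | Path, variant_map: str | Path | None = None
) -> GenotypeMatrix:
    """Samples x SNPs dosage TSV; first column is the sample id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vmap = (
        read_variant_map(variant_map)
        if variant_map is not None
        else _default_variant_map(list(df.columns))
    )
    if list(vmap["snp_id"]) != list(df.columns):
        raise InputError("variant map SNPs do not match genotype columns")
    return GenotypeMatrix(
        sample_ids=[str(s) for s in df.index],
        snp_ids=list(df.columns),
        dosage=df.to_numpy(dtype=float),
        variant_map=vmap,
    )


def write_genotypes_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(geno.dosage, index=geno.sample_ids, columns=geno.snp_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%g")


def read_plink_raw(path: str | Path, variant_map: str | Path | None = None) -> GenotypeMatrix:
    """PLINK `--recode A` additive export (whitespace-separated)."""
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise InputError(f".raw file missing columns: {missing}")
    snp_cols = [c for c in df.columns if c not in meta]
    # PLINK suffixes the counted allele, e.g. "snp1_A"; strip it
    snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    vmap = (
        read_variant_map(variant_map)
        if variant_map is not None
        else _default_variant_map(snp_ids)
    )
    return GenotypeMatrix(
        sample_ids=[str(s) for s in df["IID"]],
        snp_ids=snp_ids,
        dosage=df[snp_cols].to_numpy(dtype=float),
        variant_map=vmap,
    )


def read_taxa_tsv(path: str | Path) -> TaxaTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return TaxaTable(df)


def write_taxa_tsv(taxa: TaxaTable, path: str | Path) -> None:
    df = taxa.abundance.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_phenotypes_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return df


def write_phenotypes_tsv(phenos: pd.DataFrame, path: str | Path) -> None:
    df = phenos.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_relationship_tsv(path: str | Path, kind: str = "genomic") -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(s) for s in df.index]
    if ids != [str(c) for c in df.columns]:
        raise InputError("relationship matrix rows and columns must match")
    return RelationshipMatrix(df.to_numpy(dtype=float), ids, kind=kind)


def write_relationship_tsv(K: RelationshipMatrix, path: str | Path) -> None:
    df = pd.DataFrame(K.values, index=K.sample_ids, columns=K.sample_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def write_heritability_tsv(results: list[HeritabilityResult], path: str | Path) -> None:
    rows = [
        {
            "taxon_id": r.taxon_id,
            "h2": r.fit.ratio,
            "se": r.fit.ratio_se,
            "p": r.fit.p_value,
            "sigma_a2": r.fit.sigma_u2,
            "sigma_e2": r.fit.sigma_e2,
            "status": r.status,
            "category": r.category,
            "log10_pseudocount": r.log10_pseudocount,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_microbiability_tsv(results: list[MicrobiabilityResult], path: str | Path) -> None:
    pd.DataFrame([asdict(r) for r in results]).to_csv(path, sep="\t", index=False)


def write_classification_tsv(classes: list[TaxonClassification], path: str | Path) -> None:
    pd.DataFrame([asdict(c) for c in classes]).to_csv(path, sep="\t", index=False)
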