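"""End-to-end orchestration: simulate/load -> QC -> kernels -> heritability
-> microbiability -> GWAS -> network, with a hashed run manifest.

Every stage writes its table under the run directory; the manifest records
SHA-256 hashes of every output, the seed, and per-stage counts, so two runs
with the same config and seed are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib import metadata
from pathlib import Path

import pandas as pd

from . import io as hio
from .config import RunConfig
from .genomics import compute_grm, mantel_test, qc_genotypes
from .gwas import run_mm_gwas
from .microbiome import build_mrm, filter_and_classify_taxa, summarize_subcommunities
from .network import build_correlation_network
from .pipeline import (
    HERITABILITY_COVARIATES,
    VFA_TRAITS,
    MILK_TRAITS,
    PhenotypeTable,
    adjusted_log_abundance,
    estimate_microbiability,
    estimate_taxon_heritability,
)
from .simulate import SimulationConfig, default_trait_specs, simulate_cohort
from ._seeds import stage_seed

__all__ = ["run_full_pipeline"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _sim_config(config: RunConfig) -> SimulationConfig:
    h2 = [h for h in config.sim_h2_levels for _ in range(config.n_taxa_per_h2)]
    return SimulationConfig(
        n_individuals=config.n_individuals,
        n_snps=config.n_snps,
        taxa_h2=h2,
        taxa_prevalence=[1.0] * len(h2),
        trait_specs=default_trait_specs(config.sim_m2),
        seed=config.seed,
    )


def run_full_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    counts: dict[str, int | float] = {}
    stages: list[str] = []

    def _write(name: str, writer, *args) -> None:
        writer(*args, out / name)

    # -- inputs ------------------------------------------------------------
    if config.simulate:
        stages.append("simulate")
        geno_raw, taxa_raw, phenos_df, _truth = simulate_cohort(_sim_config(config))
        hio.write_genotypes_tsv(geno_raw, out / "genotypes.tsv")
        hio.write_variant_map(geno_raw.variant_map, out / "variant_map.tsv")
        hio.write_taxa_tsv(taxa_raw, out / "taxa.tsv")
        hio.write_phenotypes_tsv(phenos_df, out / "phenotypes.tsv")
    else:
        stages.append("load")
        geno_raw = hio.read_genotypes_tsv(config.genotype_path, config.variant_map_path)
        taxa_raw = hio.read_taxa_tsv(config.taxa_path)
        phenos_df = hio.read_phenotypes_tsv(config.phenotype_path)
    phenos = PhenotypeTable(phenos_df)

    # -- genotype QC and G -------------------------------------------------
    stages.append("qc")
    try:
        geno, report = qc_genotypes(geno_raw, thr.maf_min, thr.call_rate_min)
    except Exception as exc:
        raise StageError("qc", "empty_result", str(exc)) from exc
    counts["snps_input"] = report.n_input
    counts["snps_dropped_call_rate"] = report.n_dropped_call_rate
    counts["snps_dropped_maf"] = report.n_dropped_maf
    counts["snps_kept"] = report.n_kept

    stages.append("grm")
    G = compute_grm(geno)
    hio.write_relationship_tsv(G, out / "grm.tsv")

    # -- taxa filtering and M ---------------------------------------------
    stages.append("filter_taxa")
    taxa, classes = filter_and_classify_taxa(
        taxa_raw, thr.detection_prevalence, thr.core_prevalence
    )
    hio.write_classification_tsv(classes, out / "taxa_classification.tsv")
    counts["taxa_input"] = len(classes)
    counts["taxa_detected"] = len(taxa.taxon_ids)
    counts["taxa_core"] = sum(c.core_status == "core" for c in classes)
    counts["taxa_noncore"] = sum(c.core_status == "noncore" for c in classes)

    stages.append("mrm")
    M = build_mrm(taxa)
    hio.write_relationship_tsv(M, out / "mrm.tsv")

    stages.append("mantel")
    r, p = mantel_test(
        G, M, n_perm=thr.mantel_permutations, seed=stage_seed(config.seed, "mantel")
    )
    counts["mantel_r"] = r
    counts["mantel_p"] = p

    # -- heritability ------------------------------------------------------
    stages.append("heritability")
    cov_h2 = phenos.covariates(HERITABILITY_COVARIATES)
    h2_results, partition = estimate_taxon_heritability(taxa, G, cov_h2)
    hio.write_heritability_tsv(h2_results, out / "heritability.tsv")
    pd.DataFrame(
        [(t, s) for s, ids in partition.items() for t in ids],
        columns=["taxon_id", "status"],
    ).to_csv(out / "partition.tsv", sep="\t", index=False)
    counts["taxa_heritable"] = len(partition["heritable"])
    counts["taxa_nonheritable"] = len(partition["nonheritable"])
    counts["fits_nonconverged"] = sum(not r.fit.converged for r in h2_results)

    stages.append("subcommunities")
    summary = summarize_subcommunities(taxa, partition["heritable"])
    summary.to_csv(out / "subcommunity_summary.tsv", sep="\t")

    # -- microbiability ----------------------------------------------------
    heritable = partition["heritable"]
    nonheritable = partition["nonheritable"]
    if len(heritable) >= 2 and len(nonheritable) >= 2:
        stages.append("microbiability")
        traits = [t for t in MILK_TRAITS + VFA_TRAITS if t in phenos_df.columns]
        m2_results = estimate_microbiability(phenos, taxa, heritable, traits)
        hio.write_microbiability_tsv(m2_results, out / "microbiability.tsv")
        counts["microbiability_fits"] = len(m2_results)
    else:
        logger.warning(
            "microbiability skipped: %d heritable / %d nonheritable taxa",
            len(heritable),
            len(nonheritable),
        )
        m2_results = []

    # -- GWAS on heritable taxa -------------------------------------------
    if heritable:
        stages.append("gwas")
        adj, _ = adjusted_log_abundance(taxa.subset(heritable), cov_h2)
        gwas_table = run_mm_gwas(adj, geno, G)
        gwas_table.to_csv(out / "gwas.tsv", sep="\t", index=False)
        counts["gwas_snps_significant"] = int((gwas_table["tier"] == "significant").sum())
        counts["gwas_monomorphic_skipped"] = gwas_table.attrs["n_monomorphic_skipped"]
    else:
        logger.warning("gwas skipped: no heritable taxa")

    # -- correlation network ----------------------------------------------
    if heritable:
        stages.append("network")
        trait_cols = [t for t in MILK_TRAITS + VFA_TRAITS if t in phenos_df.columns]
        variables = pd.concat(
            [taxa.abundance[heritable], phenos_df[trait_cols]], axis=1
        )
        roles = {t: "taxon" for t in heritable}
        roles.update({t: "vfa" for t in VFA_TRAITS if t in trait_cols})
        roles.update({t: "milk_trait" for t in MILK_TRAITS if t in trait_cols})
        edges = build_correlation_network(
            variables, roles, thr.edge_rho, thr.edge_p_adj
        )
        edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
        counts["network_edges"] = len(edges)

    # -- resolved config, summary, manifest --------------------------------
    (out / "config_resolved.toml").write_text(config.to_toml_text())
    summary_lines = [
        "holoherit run summary",
        f"seed: {config.seed}",
        *(f"{k}: {v}" for k, v in counts.items()),
    ]
    (out / "summary.txt").write_text("\n".join(summary_lines) + "\n")

    try:
        version = metadata.version("holoherit")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    files = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "seed": config.seed,
        "version": version,
        "stages": stages,
        "counts": counts,
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
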