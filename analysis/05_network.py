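"""Spearman correlation network among heritable taxa, VFAs and milk traits.

Reads the cohort and step-02 partition, tests every variable pair, adjusts
p-values by BH across all pairs, and keeps edges with |rho| > 0.2 and
adjusted p < 0.05.  Writes results/network_edges.tsv.
"""

from pathlib import Path

import pandas as pd

from holoherit import build_correlation_network
from holoherit import io as hio
from holoherit.pipeline import MILK_TRAITS, VFA_TRAITS

COHORT = Path("results/cohort")
OUT = Path("results")

if __name__ == "__main__":
    taxa = hio.read_taxa_tsv(COHORT / "taxa.tsv")
    phenos = hio.read_phenotypes_tsv(COHORT / "phenotypes.tsv")
    partition = pd.read_csv(OUT / "partition.tsv", sep="\t")
    heritable = list(partition.loc[partition.status == "heritable", "taxon_id"])

    traits = [t for t in MILK_TRAITS + VFA_TRAITS if t in phenos.columns]
    variables = pd.concat([taxa.abundance[heritable], phenos[traits]], axis=1)
    roles = {t: "taxon" for t in heritable}
    roles.update({t: "vfa" for t in VFA_TRAITS if t in traits})
    roles.update({t: "milk_trait" for t in MILK_TRAITS if t in traits})

    edges = build_correlation_network(variables, roles)
    edges.to_csv(OUT / "network_edges.tsv", sep="\t", index=False)

    print(f"variables: {len(variables.columns)} "
          f"({len(heritable)} taxa, {len(traits)} traits)")
    print(f"retained edges (|rho|>0.2, p_adj<0.05): {len(edges)}")
    if len(edges):
        by_sign = edges["sign"].value_counts().to_dict()
        print(f"edge signs: {by_sign}")
    print(f"wrote {OUT/'network_edges.tsv'}")
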