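"""Microbiability and mean microbiability of the heritable and nonheritable
subcommunities for every trait.

Reads the cohort and the heritable/nonheritable partition from step 02,
rebuilds the microbial kernel per subcommunity, fits the trait mixed model
(covariates: subcohort, parity, age, days-in-milk), and reports m2 and the
per-taxon average beta2 = m2 / o.  Writes results/microbiability.tsv.
"""

from pathlib import Path

import pandas as pd

from holoherit import (
    PhenotypeTable,
    estimate_microbiability,
    filter_and_classify_taxa,
    percent_round,
)
from holoherit import io as hio

COHORT = Path("results/cohort")
OUT = Path("results")

if __name__ == "__main__":
    taxa_raw = hio.read_taxa_tsv(COHORT / "taxa.tsv")
    phenos = PhenotypeTable(hio.read_phenotypes_tsv(COHORT / "phenotypes.tsv"))
    partition = pd.read_csv(OUT / "partition.tsv", sep="\t")
    heritable = list(partition.loc[partition.status == "heritable", "taxon_id"])

    taxa, _ = filter_and_classify_taxa(taxa_raw)
    results = estimate_microbiability(phenos, taxa, heritable)
    hio.write_microbiability_tsv(results, OUT / "microbiability.tsv")

    print(f"heritable subcommunity: {len(heritable)} taxa")
    print("trait           group          m2      beta2(%)")
    for r in results:
        print(f"{r.trait:<15s} {r.group:<13s} {r.m2:5.3f}   "
              f"{percent_round(r.beta2):.2f}")
    print(f"wrote {OUT/'microbiability.tsv'}")
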