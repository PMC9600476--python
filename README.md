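# holoherit

Host-genetics × rumen-microbiome variance-component analysis for dairy
cattle cohorts: which microbial taxa are heritable, and how much do the
heritable and nonheritable subcommunities each contribute to lactation
performance?

The package implements, as a tested pipeline over synthetic or file-based
cohorts:

- **Per-taxon narrow-sense heritability** from an animal model,
  y\* = 1μ + a + e with a ~ N(0, G σa²), h² = σa²/(σa²+σe²), where G is the
  VanRaden genomic relationship matrix from QC'd SNP dosages. Taxa with
  h²/SE > 2 and p < 0.05 are classified heritable (high if h² > 0.4,
  moderate if 0.2 < h² < 0.4).
- **Microbiability** of lactation and volatile-fatty-acid (VFA) traits,
  y = Xc + m + e with m ~ N(0, M σm²), m² = σm²/(σm²+σe²), where
  M = (1/q)OOᵀ is the microbiota relationship matrix built from
  column-standardized log(relative abundance + 1) over a subcommunity of q
  taxa — and the **mean microbiability** β² = m²/o, the average
  single-taxon contribution.
- **Mixed-model GWAS** (P3D/EMMAX-style) of heritable taxa against SNPs
  with per-taxon Benjamini–Hochberg FDR, and **Spearman correlation
  networks** among taxa, VFAs and milk traits (|rho| > 0.2, adjusted
  p < 0.05).
- A **synthetic cohort generator** that plants known h², m² and SNP
  effects, so every estimator is validated by parameter recovery without
  any data download.

Intended users: quantitative geneticists and microbiome researchers who
want a transparent, fully testable reimplementation of this analysis
chain rather than a black-box mixed-model package.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort of 400 animals × 2,000 SNPs with 60 taxa planted at h² ∈
{0, 0.3, 0.6}:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_heritability.py
```

prints

```
cohort: 400 animals, 2000 SNPs, 61 taxa columns (incl. filler)
mean GRM diagonal: 0.998 (~1 expected under HWE)
...
detected taxa: 61; heritable: 31
planted h2=0.0: mean estimate 0.075 over 20 taxa
planted h2=0.3: mean estimate 0.276 over 20 taxa
planted h2=0.6: mean estimate 0.592 over 20 taxa
heritable categories: {'high': 25, 'moderate': 6}
```

i.e. the animal model recovers each planted heritability level to within a
few hundredths, and taxa simulated with no genetic component are almost
never called heritable. `03_microbiability.py`, `04_gwas.py` and
`05_network.py` continue the chain: microbiability per subcommunity and
trait (with β² = m²/o per taxon), the SNP scan on the heritable taxa, and
the trait–taxa correlation network, each writing its table under
`results/`.

The same chain is available as a library call
(`holoherit.run_full_pipeline`) or from the shell:

```bash
holoherit run --seed 7 --out-dir results/run7
```

which writes every stage table plus a manifest of SHA-256 hashes — two
runs with the same config and seed are verifiably identical.

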