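# Methods

`holoherit` estimates how much of the variation in a rumen microbial
community is shaped by host genetics, and how much of the variation in
lactation and fermentation traits is in turn explained by that community.
This note records the models, the numerical choices, and what the synthetic
cohort does and does not emulate.

## Models

### Per-taxon heritability (animal model)

For each detected taxon, relative abundances are transformed as
log10(p + δ), with δ equal to half the smallest nonzero proportion in the
whole table — a common microbiome pseudocount that keeps zeros finite
without dominating the detected values. δ is recorded in every result row.

Estimation is two-stage, as is conventional for microbial phenotypes:

1. OLS adjustment of the log abundance for fixed effects — subcohort (two
   levels), parity, age, days-in-milk, and ruminal pH. pH is treated as a
   fixed covariate here; an argument can be made for modelling it as a
   random cofactor, but the fixed-effect form is the one implemented.
2. An intercept-only linear mixed model on the residuals,
   y* = 1μ + a + e, a ~ N(0, G σa²), e ~ N(0, I σe²), with G the genomic
   relationship matrix. Narrow-sense heritability is
   h² = σa² / (σa² + σe²).

A taxon is called *heritable* when h²/SE > 2 and the boundary
likelihood-ratio p < 0.05; heritable taxa are *high* (h² > 0.4),
*moderate* (0.2 < h² ≤ 0.4), or *low*.

### Microbiability (single stage)

Trait models carry their covariates inside the mixed model:
y = Xc + m + e, m ~ N(0, M σm²), with fixed effects subcohort, parity,
age and days-in-milk (no pH — the trait model's covariate list differs
deliberately from the heritability stage). Microbiability is
m² = σm² / (σm² + σe²), and the *mean microbiability* β² = m² / o spreads a
subcommunity's total contribution uniformly over its o taxa, under the
assumption that every taxon's standardized effect has equal variance.

The microbial kernel is M = (1/q) O Oᵀ, where O column-standardizes
log(proportion + 1) over the q taxa of the subcommunity. The kernel is
rebuilt per subcommunity (heritable vs nonheritable) rather than sliced
from a global O: column standardization is subset-independent and the 1/q
scaling implies per-subset q, so rebuilding is both simpler and exact.
Two consequences worth knowing:

- trace(M) = n − 1 for any valid input (sample SD uses the n−1
  denominator) — used as a self-check throughout the tests;
- M is exactly invariant to the base of the logarithm.

The "+1" is applied to proportions in [0, 1] as such, not to percentages;
using percentages would change M nonlinearly. Zero-variance columns are
dropped with a warning and q reduced accordingly.

### Genomic kernel and QC

G follows VanRaden's first method with sample allele frequencies:
G = ZZᵀ / (2 Σ f(1−f)) after centring each SNP by 2f. QC keeps SNPs with
call rate strictly above 0.90 and MAF strictly above 0.05 (call-rate
filter first, then MAF on non-missing calls, then per-SNP mean
imputation; the order is a package choice). The association between G and
M is assessed with a Mantel test on the strictly-lower-triangle entries of
the similarity matrices themselves (not distances), with joint row/column
permutation of one matrix, one-sided upper tail, add-one correction, and
9,999 permutations by default.

### REML engine

Both ratios are estimated by the same single-kernel profile-REML engine.
The response is projected onto an orthonormal basis of the fixed-effect
complement (this is exactly the restricted likelihood), the projected
kernel is eigendecomposed once, and the log-likelihood becomes a 1-D
function of the ratio r with the total variance profiled out in closed
form. Numerical choices:

- ratio box [1e-6, 1 − 1e-6]; optima at the box edge are flagged
  (`at_boundary`) to avoid exact-boundary degeneracies;
- 64-point log-spaced grid (dense toward both ends) bracketing a bounded
  Brent refinement with tolerance 1e-8;
- SE from the curvature of the profile log-likelihood at the optimum
  (central differences); a flat or non-concave profile yields SE = ∞ and
  hence a nonheritable call — a conservative failure mode. Software that
  uses average-information REML will report slightly different SEs; the
  difference is documented, not chased;
- p-value against σu² = 0 from the boundary LRT with the 50:50
  χ²₀/χ²₁ mixture, the standard reference distribution for a variance
  component on its boundary;
- projected-kernel eigenvalues below −1e-8 (relative) raise an error;
  small negatives above that are clipped to zero.

The workspace (projection + eigendecomposition) is computed once per
(kernel, design) pair and reused across responses, which is what makes the
per-taxon scans cheap.

### GWAS

Heritable taxa are scanned with the P3D/EMMAX approximation: the null
kernel model is fitted once per taxon; each SNP (recoded −1/0/1 around
heterozygotes) is then tested by GLS with the null variance components
held fixed. The Wald statistic is referred to t with n − 2 degrees of
freedom (intercept + SNP; taxon values enter pre-adjusted, so the fixed
part is intercept-only). Monomorphic-in-sample SNPs are skipped and
counted. BH adjustment is per taxon; FDR < 0.01 is significant and
[0.01, 0.05) suggestive. An exact mode refits REML per SNP and exists for
small-n sanity checks: on such data the two modes rank the top hits
identically in ≥ 90% of seeded replicates.

### Correlation network

Spearman's rho over all unordered variable pairs (taxa, VFAs, milk
traits), pairwise-complete for missing values, two-sided p from the
large-sample t approximation with average-rank ties, BH over all pairs
tested in the run (the adjustment family is a package choice), and edges
kept when |rho| > 0.2 strictly and adjusted p < 0.05. A permutation p is
available for pairs with fewer than 10 complete observations.

## Synthetic cohort

The generator emulates the study design the pipeline targets — a
mid-lactation dairy-cow cohort — at configurable scale; defaults are 400
animals, 2,000 SNPs in HWE with MAF uniform on [0.05, 0.5] mapped
round-robin to the 29 bovine autosomes, and 60 taxa with planted h² of 0,
0.3 and 0.6 (20 each).

- Taxa: latent log abundance x = μ + a + ε with a drawn through a
  symmetric eigen square-root of the realized G (eigenvalues clipped at 0,
  tolerance 1e-8) and var(a)/var(x) equal to the planted h². Abundances
  are exp(x); rows are closed to proportions by a filler "remainder"
  column so the planted columns keep their exact values (the filler
  absorbs ~70% of each row, standing in for the undetected bulk of a real
  community). Zero inflation truncates the smallest latent values so
  realized prevalence is exact and reproducible — but truncation biases
  realized h², so zero-inflated taxa are used only for filter and
  classification tests, never for recovery checks.
- Phenotypes: covariates follow the cohort description (subcohort ~72/28,
  parity 1–5 with mean ≈ 2.6, days-in-milk uniform on [125, 185], pH
  uniform on [5.5, 7.0], age tied loosely to parity); traits are
  fixed effects + O w + e with w ~ N(0, σm²/q) over the standardized
  log-abundance matrix of the planted taxa, so the generating covariance
  is exactly σm² M. Protein and fat yields are contents × milk yield, and
  energy-corrected milk is 0.3246·MY + 13.86·MFY + 7.04·MPY. The default
  planted m² is 0.30 for every base trait.
- Seeding: one root seed expands to per-stage child streams via
  `SeedSequence(seed, spawn_key=(stage,))`, so any stage regenerates
  bit-identically in isolation.

What the generator does **not** emulate: compositional coupling between
planted taxa (columns are independent given G), sequencing depth and
count noise, taxon-taxon ecological interactions, linkage disequilibrium
(SNPs are independent), and population structure. Passing recovery tests
therefore shows the estimators are correct under the stated model, not
that real rumen data meet that model.

## Problem sizes and tolerances in the validation suite

Recovery checks run at the cohort scale above: 30 replicates for
heritability (mean estimate within ±0.07 of each planted level;
false-heritable rate at h² = 0 at most 10%), 20 replicates for
microbiability at q = 100 (±0.08; null trait mean ≤ 0.05), 20 replicates
for the planted-SNP scan (top hit at FDR < 0.01 in ≥ 90%). The REML
engine is additionally pinned to two independent oracles on fixed
8-animal family designs: an exhaustive 1e-4 grid scan of the restricted
likelihood (agreement within 1e-3) and a direct multivariate-normal
evaluation of the criterion at fixed variance components (within 1e-8).
These sizes keep the whole suite in the tens of seconds while leaving
Monte-Carlo error well inside the asserted bands.

## Known limitations

- SEs are profile-curvature SEs, not average-information SEs; p-values
  are boundary-LRT, matching no particular proprietary implementation.
- The mean-microbiability definition divides by the subcommunity size
  actually entering the kernel (after zero-variance drops).
- The two-stage heritability pipeline ignores uncertainty from the OLS
  pre-adjustment; with n ≫ covariates this is negligible.
- No multi-kernel (joint G + M) model is provided: the heritability and
  microbiability fits are intentionally separate single-kernel models.
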