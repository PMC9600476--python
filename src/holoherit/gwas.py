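"""Mixed-model association of taxa against SNPs with per-taxon BH FDR.

The default follows the P3D/EMMAX strategy: for each taxon the null kernel
model (intercept + polygenic effect against G) is fitted once by REML; each
SNP, recoded to -1/0/1 around heterozygotes, is then tested by generalized
least squares holding the null variance components fixed.  The Wald
statistic is referred to a t distribution with n - 2 degrees of freedom
(intercept + SNP).  An exact mode refits the variance components per SNP
and is intended only for small-n sanity checks.

P values are adjusted within taxon by Benjamini-Hochberg; associations are
*significant* at FDR < 0.01 and *suggestive* at FDR in [0.01, 0.05).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomics import GenotypeMatrix, InputError, RelationshipMatrix
from .varcomp import RemlWorkspace

__all__ = ["run_mm_gwas", "bh_adjust", "FDR_SIGNIFICANT", "FDR_SUGGESTIVE"]

logger = logging.getLogger(__name__)

FDR_SIGNIFICANT = 0.01
FDR_SUGGESTIVE = 0.05


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _tier(fdr: float) -> str:
    if fdr < FDR_SIGNIFICANT:
        return "significant"
    if fdr < FDR_SUGGESTIVE:
        return "suggestive"
    return "ns"


def run_mm_gwas(
    taxon_values: pd.DataFrame,
    genotypes: GenotypeMatrix,
    G: RelationshipMatrix,
    exact: bool = False,
) -> pd.DataFrame:
    """Association scan of pre-adjusted taxon values against every SNP.

    ``taxon_values`` holds one column per taxon (values already adjusted for
    fixed effects), indexed by sample id in the order of ``genotypes`` and
    ``G``.  Returns one row per (SNP, taxon) sorted by (taxon, fdr) with
    columns snp_id, chrom, bp, taxon_id, beta, se, p, fdr, tier.
    Monomorphic-in-sample SNPs are skipped; the count is logged and stored
    in the result's ``attrs['n_monomorphic_skipped']``.
    """
    ids = list(taxon_values.index)
    if ids != list(genotypes.sample_ids) or ids != list(G.sample_ids):
        raise InputError("taxon values, genotypes and G must share sample order")
    n = len(ids)
    S = genotypes.dosage - 1.0  # -1/0/1 coding for AA/AB/BB
    mono = S.std(axis=0) == 0
    n_mono = int(mono.sum())
    if n_mono:
        logger.info("skipping %d monomorphic-in-sample SNPs", n_mono)
    keep = np.flatnonzero(~mono)
    S = S[:, keep]
    snp_ids = [genotypes.snp_ids[j] for j in keep]
    vmap = genotypes.variant_map.iloc[keep]

    lam, Q = np.linalg.eigh(G.values)
    lam = np.clip(lam, 0.0, None)
    ones_r = Q.T @ np.ones(n)
    S_r = Q.T @ S

    ws_null = RemlWorkspace(G)  # intercept-only null model, shared across taxa
    frames = []
    for taxon in taxon_values.columns:
        y = taxon_values[taxon].to_numpy(dtype=float)
        null = ws_null.fit(y)
        if not null.converged:
            logger.warning("taxon %s: null kernel fit non-converged; skipped", taxon)
            continue
        if exact:
            beta, se = _scan_exact(y, S, G)
        else:
            beta, se = _scan_p3d(
                Q.T @ y, ones_r, S_r, null.sigma_u2 * lam + null.sigma_e2
            )
        tstat = beta / se
        p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
        fdr = bh_adjust(p)
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": snp_ids,
                    "chrom": vmap["chrom"].to_numpy(),
                    "bp": vmap["bp"].to_numpy(),
                    "taxon_id": taxon,
                    "beta": beta,
                    "se": se,
                    "p": p,
                    "fdr": fdr,
                    "tier": [_tier(f) for f in fdr],
                }
            )
        )
    if not frames:
        out = pd.DataFrame(
            columns=["snp_id", "chrom", "bp", "taxon_id", "beta", "se", "p", "fdr", "tier"]
        )
    else:
        out = pd.concat(frames, ignore_index=True)
        out = out.sort_values(["taxon_id", "fdr", "p", "snp_id"], kind="mergesort")
        out = out.reset_index(drop=True)
    out.attrs["n_monomorphic_skipped"] = n_mono
    return out


def _scan_p3d(
    y_r: np.ndarray, ones_r: np.ndarray, S_r: np.ndarray, v: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """GLS of y on [1, snp] for every SNP at fixed V = diag(v) in G's eigenbasis.

    The 2x2 normal equations are solved in closed form, vectorized over SNPs;
    V is treated as known, so cov(beta_hat) = (W' V^-1 W)^-1 exactly.
    """
    d = 1.0 / v
    a11 = float(np.sum(d * ones_r**2))
    b1 = float(np.sum(d * ones_r * y_r))
    a12 = (d * ones_r) @ S_r
    a22 = d @ (S_r**2)
    b2 = (d * y_r) @ S_r
    det = a11 * a22 - a12**2
    beta = (a11 * b2 - a12 * b1) / det
    se = np.sqrt(a11 / det)
    return beta, se


def _scan_exact(
    y: np.ndarray, S: np.ndarray, G: RelationshipMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP REML refit: variance components re-estimated under [1, snp]."""
    n, p = S.shape
    beta = np.empty(p)
    se = np.empty(p)
    for j in range(p):
        X = np.column_stack([np.ones(n), S[:, j]])
        ws = RemlWorkspace(G, X)
        fit = ws.fit(y)
        V = fit.sigma_u2 * G.values + fit.sigma_e2 * np.eye(n)
        Vi = np.linalg.inv(V)
        A = X.T @ Vi @ X
        bhat = np.linalg.solve(A, X.T @ Vi @ y)
        cov = np.linalg.inv(A)
        beta[j] = bhat[1]
        se[j] = np.sqrt(cov[1, 1])
    return beta, se
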