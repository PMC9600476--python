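"""Genotype QC, the genomic relationship matrix, and the Mantel test.

The genomic relationship matrix (GRM, ``G``) follows VanRaden's first method:
each SNP dosage column is centred by twice its sample allele frequency and

    G = Z Z' / (2 * sum_k p_k (1 - p_k))

so that under Hardy-Weinberg equilibrium the diagonal averages ~1 and
off-diagonals estimate twice the kinship coefficient.  QC mirrors the usual
chip pipeline: per-SNP call rate, then minor allele frequency on the
non-missing calls, then per-SNP mean imputation of the survivors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "RelationshipMatrix",
    "QCReport",
    "qc_genotypes",
    "compute_grm",
    "mantel_test",
]


class InputError(ValueError):
    """Malformed or inconsistent user input."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs additive dosages with a variant map.

    ``dosage`` holds values in {0, 1, 2} with NaN for missing calls
    (pre-QC only).  ``variant_map`` has one row per SNP with columns
    ``snp_id``, ``chrom``, ``bp``.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    dosage: np.ndarray  # float (n, p), NaN = missing
    variant_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, p = self.dosage.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != p:
            raise InputError("id lengths do not match dosage shape")
        if len(set(self.sample_ids)) != n or len(set(self.snp_ids)) != p:
            raise InputError("sample and SNP ids must be unique")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise InputError("dosages must be 0/1/2 or missing")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Per-SNP sample frequency of the counted allele (non-missing calls)."""
        return np.nanmean(self.dosage, axis=0) / 2.0

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snp_ids=[self.snp_ids[i] for i in np.flatnonzero(keep)]
            if keep.dtype == bool
            else [self.snp_ids[i] for i in keep],
            dosage=self.dosage[:, keep],
            variant_map=self.variant_map.iloc[np.flatnonzero(keep) if keep.dtype == bool else keep].reset_index(drop=True),
        )


@dataclass
class RelationshipMatrix:
    """Symmetric n x n similarity kernel among individuals (genomic or microbial)."""

    values: np.ndarray
    sample_ids: list[str]
    kind: str = "genomic"  # "genomic" | "microbial"

    _SYM_TOL = 1e-10
    _PSD_TOL = -1e-8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise InputError("kernel shape does not match sample ids")
        if not np.allclose(self.values, self.values.T, atol=self._SYM_TOL):
            raise InputError("kernel is not symmetric")
        self.values = (self.values + self.values.T) / 2.0

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def check_psd(self) -> None:
        w = np.linalg.eigvalsh(self.values)
        if w.min() < self._PSD_TOL * max(1.0, abs(w.max())):
            raise InputError(f"kernel not positive semi-definite (min eig {w.min():.3g})")

    def reorder(self, sample_ids: list[str]) -> "RelationshipMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return RelationshipMatrix(self.values[np.ix_(idx, idx)], list(sample_ids), self.kind)


@dataclass
class QCReport:
    n_input: int
    n_dropped_call_rate: int
    n_dropped_maf: int
    n_imputed_entries: int

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_dropped_call_rate - self.n_dropped_maf


def qc_genotypes(
    raw: GenotypeMatrix, maf_min: float = 0.05, call_rate_min: float = 0.90
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter SNPs by call rate then MAF; mean-impute remaining missing calls.

    A SNP is kept only if its call rate is strictly greater than
    ``call_rate_min`` and its minor allele frequency (on non-missing calls)
    is strictly greater than ``maf_min``.
    """
    if raw.n_samples < 2:
        raise InputError("need at least 2 samples for QC")
    X = raw.dosage
    call_rate = 1.0 - np.isnan(X).mean(axis=0)
    pass_cr = call_rate > call_rate_min

    with np.errstate(invalid="ignore"):
        f = np.nanmean(X, axis=0) / 2.0
    maf = np.minimum(f, 1.0 - f)
    pass_maf = np.nan_to_num(maf, nan=0.0) > maf_min

    keep = pass_cr & pass_maf
    n_cr = int((~pass_cr).sum())
    # MAF drops counted among call-rate survivors so the two tallies partition
    n_maf = int((pass_cr & ~pass_maf).sum())
    if not keep.any():
        raise InputError(
            f"all {raw.n_snps} SNPs dropped (call rate: {n_cr}, MAF: {n_maf})"
        )

    out = raw.subset_snps(keep)
    miss = np.isnan(out.dosage)
    n_imp = int(miss.sum())
    if n_imp:
        col_mean = np.nanmean(out.dosage, axis=0)
        dosage = np.where(miss, np.broadcast_to(col_mean, out.dosage.shape), out.dosage)
        # imputed entries are no longer integral; store without re-validation
        out = GenotypeMatrix.__new__(GenotypeMatrix)
        out.sample_ids = list(raw.sample_ids)
        out.snp_ids = [raw.snp_ids[i] for i in np.flatnonzero(keep)]
        out.dosage = dosage
        out.variant_map = raw.variant_map.iloc[np.flatnonzero(keep)].reset_index(drop=True)
    report = QCReport(raw.n_snps, n_cr, n_maf, n_imp)
    return out, report


def compute_grm(genotypes: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix from QC'd genotypes."""
    X = genotypes.dosage
    if np.isnan(X).any():
        raise InputError("genotypes contain missing calls; run QC first")
    if X.shape[1] < 1:
        raise InputError("no SNPs")
    f = X.mean(axis=0) / 2.0
    if np.any((f <= 0.0) | (f >= 1.0)):
        raise InputError("monomorphic SNPs present; remove them in QC")
    Z = X - 2.0 * f
    denom = 2.0 * float(np.sum(f * (1.0 - f)))
    G = (Z @ Z.T) / denom
    return RelationshipMatrix(G, list(genotypes.sample_ids), kind="genomic")


def mantel_test(
    A: RelationshipMatrix,
    B: RelationshipMatrix,
    n_perm: int = 9999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation Mantel test between two similarity kernels.

    The statistic is the Pearson correlation of the strictly-lower-triangle
    entries.  Rows and columns of ``B`` are permuted jointly; the one-sided
    upper-tail p-value uses the add-one correction
    ``p = (1 + #{r_perm >= r_obs}) / (1 + n_perm)``.
    """
    if A.sample_ids != B.sample_ids:
        raise InputError("kernels must share the same samples in the same order")
    if n_perm < 99:
        raise InputError("n_perm must be at least 99")
    n = A.n
    il = np.tril_indices(n, k=-1)
    a = A.values[il]
    r_obs = _pearson(a, B.values[il])

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = B.values[np.ix_(perm, perm)][il]
        if _pearson(a, bp) >= r_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return float(r_obs), float(p)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x @ x) * (y @ y))
    if denom == 0:
        raise InputError("zero variance in kernel off-diagonals")
    return float((x @ y) / denom)
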