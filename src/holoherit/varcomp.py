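"""Single-kernel REML engine for heritability and microbiability.

Model: y = X b + u + e with u ~ N(0, K su2) and e ~ N(0, I se2) for a
positive semi-definite similarity kernel K (genomic G or microbial M).
The quantity of interest is the variance ratio su2 / (su2 + se2) — the
narrow-sense heritability h2 when K = G, the microbiability m2 when K = M.

Estimation uses the classic one-eigendecomposition trick: project y onto an
orthonormal basis of the complement of the fixed-effect column space (this
is exactly the restricted likelihood), eigendecompose the projected kernel
once, and the REML log-likelihood becomes a cheap 1-D function of the ratio
r after profiling out the total variance:

    v_i(r)   = r * lam_i + (1 - r)
    s2(r)    = mean_i z_i^2 / v_i(r)
    2 ll(r)  = -[ m log(2 pi) + m log s2(r) + sum_i log v_i(r) + m ]

maximized over r in [1e-6, 1 - 1e-6] by a coarse log-spaced grid followed
by bounded scalar refinement.  The standard error of the ratio comes from
the curvature of this profile log-likelihood at the optimum; the p-value
against su2 = 0 is the boundary likelihood-ratio test with the 50:50
chi2(0)/chi2(1) mixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .genomics import InputError, RelationshipMatrix

__all__ = [
    "VarCompFit",
    "RemlWorkspace",
    "adjust_fixed_effects",
    "build_design",
    "fit_reml_lmm",
    "reml_loglik",
    "classify_heritable",
    "RATIO_LO",
    "RATIO_HI",
]

RATIO_LO = 1e-6
RATIO_HI = 1.0 - 1e-6
_GRID_SIZE = 64
_EIG_TOL = -1e-8


@dataclass
class VarCompFit:
    """One REML fit: variance components, the ratio, its SE and boundary-LRT p."""

    sigma_u2: float
    sigma_e2: float
    ratio: float
    ratio_se: float
    loglik_reml: float
    p_value: float
    converged: bool
    n_used: int
    at_boundary: bool = False


def build_design(covariates: pd.DataFrame | None, n: int | None = None) -> np.ndarray:
    """Design matrix with intercept; categorical columns dummy-coded (drop-first).

    Raises when the design is rank deficient, naming columns that add no rank.
    """
    if covariates is None:
        if n is None:
            raise InputError("need n for an intercept-only design")
        return np.ones((n, 1))
    if covariates.isna().any().any():
        raise InputError("covariates contain missing values")
    cols: list[np.ndarray] = [np.ones(len(covariates))]
    names = ["intercept"]
    for c in covariates.columns:
        s = covariates[c]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=c, drop_first=True, dtype=float)
            for dc in dummies.columns:
                cols.append(dummies[dc].to_numpy())
                names.append(dc)
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack(cols)
    # identify columns that do not increase rank
    offenders = []
    rank = 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, : j + 1])
        if r == rank:
            offenders.append(names[j])
        rank = r
    if offenders:
        raise InputError(f"rank-deficient design; collinear columns: {offenders}")
    return X


def adjust_fixed_effects(y: np.ndarray, covariates: pd.DataFrame | None) -> np.ndarray:
    """OLS residuals of y on [intercept | covariates] (pre-correction stage).

    Categorical covariates are dummy-coded.  The returned vector is
    orthogonal to every design column.
    """
    y = np.asarray(y, dtype=float)
    X = build_design(covariates, n=len(y))
    if X.shape[0] != len(y):
        raise InputError("covariate rows do not match y")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


class RemlWorkspace:
    """Precomputed REML machinery for one (kernel, fixed design) pair.

    Building the workspace costs one eigendecomposition; each subsequent
    :meth:`fit` on a new response is a fast 1-D optimization.  Reuse it when
    fitting many taxa against the same kernel.
    """

    def __init__(self, kernel: RelationshipMatrix | np.ndarray, fixed: np.ndarray | None = None):
        K = kernel.values if isinstance(kernel, RelationshipMatrix) else np.asarray(kernel, float)
        n = K.shape[0]
        X = np.ones((n, 1)) if fixed is None else np.asarray(fixed, float)
        if X.ndim != 2 or X.shape[0] != n:
            raise InputError("fixed design shape does not match kernel")
        p = np.linalg.matrix_rank(X)
        if p != X.shape[1]:
            raise InputError("fixed design is rank deficient")
        if n < X.shape[1] + 2:
            raise InputError("need n >= #fixed effects + 2")
        U2 = linalg.null_space(X.T)  # orthonormal, n x (n - p)
        Kt = U2.T @ K @ U2
        lam, V = np.linalg.eigh((Kt + Kt.T) / 2.0)
        scale = max(1.0, float(lam.max())) if lam.size else 1.0
        if lam.min() < _EIG_TOL * scale:
            raise InputError(f"kernel not PSD within tolerance (min eig {lam.min():.3g})")
        self.n = n
        self.m = U2.shape[1]
        self.lam = np.clip(lam, 0.0, None)
        self._rot = V.T @ U2.T  # maps y -> z

    # -- likelihood --------------------------------------------------------

    def _z2(self, y: np.ndarray) -> np.ndarray:
        z = self._rot @ np.asarray(y, float)
        return z * z

    def profile_loglik(self, y: np.ndarray, ratio: float) -> float:
        """REML log-likelihood at the given ratio, total variance profiled out."""
        return self._profile(self._z2(y), ratio)

    def _profile(self, z2: np.ndarray, r: float) -> float:
        v = r * self.lam + (1.0 - r)
        if np.any(v <= 0):
            return -np.inf
        s2 = float(np.mean(z2 / v))
        if s2 <= 0:
            return -np.inf
        m = self.m
        return -0.5 * (m * np.log(2 * np.pi) + m * np.log(s2) + float(np.sum(np.log(v))) + m)

    def loglik(self, y: np.ndarray, sigma_u2: float, sigma_e2: float) -> float:
        """REML log-likelihood at fixed variance components (no profiling)."""
        z2 = self._z2(y)
        v = sigma_u2 * self.lam + sigma_e2
        if np.any(v <= 0):
            return -np.inf
        return -0.5 * (
            self.m * np.log(2 * np.pi) + float(np.sum(np.log(v))) + float(np.sum(z2 / v))
        )

    # -- fitting -----------------------------------------------------------

    @staticmethod
    def _ratio_grid() -> np.ndarray:
        # log-spaced toward both ends of the box so near-zero and near-one
        # optima are bracketed tightly
        half = _GRID_SIZE // 2
        lo = np.geomspace(RATIO_LO, 0.5, half)
        hi = 1.0 - np.geomspace(1.0 - RATIO_HI, 0.5, half)[::-1]
        return np.unique(np.concatenate([lo, hi]))

    def fit(self, y: np.ndarray) -> VarCompFit:
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise InputError("response length does not match kernel")
        if np.var(y) == 0:
            raise InputError("response has zero variance")
        z2 = self._z2(y)
        grid = self._ratio_grid()
        vals = np.array([self._profile(z2, r) for r in grid])
        k = int(np.argmax(vals))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda r: -self._profile(z2, r),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        r_hat = float(res.x)
        ll_hat = float(-res.fun)
        converged = bool(res.success)

        v = r_hat * self.lam + (1.0 - r_hat)
        s2 = float(np.mean(z2 / v))
        sigma_u2 = r_hat * s2
        sigma_e2 = (1.0 - r_hat) * s2

        # SE from profile curvature (central differences)
        h = min(1e-4, r_hat - RATIO_LO, RATIO_HI - r_hat)
        at_boundary = (r_hat - RATIO_LO < 1e-5) or (RATIO_HI - r_hat < 1e-5)
        if h < 1e-8:
            se = np.inf
        else:
            d2 = (
                self._profile(z2, r_hat + h)
                - 2.0 * ll_hat
                + self._profile(z2, r_hat - h)
            ) / h**2
            se = float(np.sqrt(-1.0 / d2)) if d2 < 0 else np.inf

        # boundary LRT against sigma_u2 = 0: 0.5 chi2_0 + 0.5 chi2_1
        ll0 = self._profile(z2, 0.0)
        lr = max(0.0, 2.0 * (ll_hat - ll0))
        p = 0.5 * float(stats.chi2.sf(lr, df=1))

        return VarCompFit(
            sigma_u2=sigma_u2,
            sigma_e2=sigma_e2,
            ratio=r_hat,
            ratio_se=se,
            loglik_reml=ll_hat,
            p_value=p,
            converged=converged,
            n_used=self.n,
            at_boundary=at_boundary,
        )


def fit_reml_lmm(
    y: np.ndarray,
    kernel: RelationshipMatrix,
    fixed: pd.DataFrame | np.ndarray | None = None,
) -> VarCompFit:
    """Fit the single-kernel mixed model by profile REML.

    ``fixed`` may be a covariate DataFrame (dummy-coded, intercept added), a
    ready design matrix, or None for intercept only.
    """
    if isinstance(fixed, pd.DataFrame):
        X = build_design(fixed, n=len(y))
    elif fixed is None:
        X = None
    else:
        X = np.asarray(fixed, float)
    return RemlWorkspace(kernel, X).fit(np.asarray(y, float))


def reml_loglik(
    y: np.ndarray,
    kernel: RelationshipMatrix,
    sigma_u2: float,
    sigma_e2: float,
    fixed: np.ndarray | None = None,
) -> float:
    """REML log-likelihood at fixed variance components.

    Defined as the log density of the projection of y onto an orthonormal
    basis of the fixed-effect complement — directly comparable to an
    independent multivariate-normal evaluation on the projected data.
    """
    return RemlWorkspace(kernel, fixed).loglik(np.asarray(y, float), sigma_u2, sigma_e2)


def classify_heritable(fit: VarCompFit) -> tuple[str, str]:
    """Significance call and magnitude category for one variance-ratio fit.

    A taxon is *heritable* when ratio / SE > 2 and the boundary-LRT p < 0.05.
    Heritable taxa are *high* (> 0.4), *moderate* (0.2, 0.4], or *low*.
    """
    if not fit.converged:
        raise InputError("cannot classify a non-converged fit")
    heritable = (
        np.isfinite(fit.ratio_se)
        and fit.ratio_se > 0
        and fit.ratio / fit.ratio_se > 2.0
        and fit.p_value < 0.05
    )
    if not heritable:
        return "nonheritable", ""
    if fit.ratio > 0.4:
        return "heritable", "high"
    if fit.ratio > 0.2:
        return "heritable", "moderate"
    return "heritable", "low"
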