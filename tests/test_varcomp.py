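"""The REML engine: fixed-effect adjustment, profile-likelihood fits,
oracle equivalence and the heritable-classification rule."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

from holoherit import InputError, adjust_fixed_effects, fit_reml_lmm, reml_loglik
from holoherit.varcomp import RemlWorkspace, VarCompFit, build_design, classify_heritable

from conftest import family_kernel


def _frozen_y(seed, n=8):
    return np.round(np.random.default_rng(seed).standard_normal(n) * 2, 3)


def oracle_grid_ratio(y, K, resolution=1e-4):
    """Exhaustive grid maximization of the REML log-likelihood over the ratio.

    Independent path: explicit null-space projection, direct linear solves
    (no eigendecomposition), total variance profiled by the MVN stationarity
    condition s2 = z' C(r)^-1 z / m.
    """
    n = len(y)
    U2 = linalg.null_space(np.ones((1, n)))
    z = U2.T @ y
    m = len(z)
    C0 = U2.T @ K @ U2
    I = np.eye(m)
    best_r, best_ll = None, -np.inf
    for r in np.arange(resolution, 1.0, resolution):
        C = r * C0 + (1 - r) * I
        s2 = float(z @ np.linalg.solve(C, z)) / m
        sign, logdet = np.linalg.slogdet(C)
        ll = -0.5 * (m * np.log(2 * np.pi * s2) + logdet + m)
        if ll > best_ll:
            best_ll, best_r = ll, r
    return best_r


class TestAdjustFixedEffects:
    def test_intercept_only_is_centering(self):
        y = np.array([1.0, 2.0, 4.0, 9.0])
        np.testing.assert_allclose(adjust_fixed_effects(y, None), y - y.mean())

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(0)
        cov = pd.DataFrame(
            {
                "subcohort": rng.choice(["a", "b"], 30),
                "parity": rng.integers(1, 6, 30).astype(float),
                "age": rng.uniform(2, 8, 30),
                "ph": rng.uniform(5.5, 7, 30),
            }
        )
        y = rng.standard_normal(30)
        res = adjust_fixed_effects(y, cov)
        X = build_design(cov)
        np.testing.assert_allclose(X.T @ res, 0.0, atol=1e-8)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(1)
        cov = pd.DataFrame(rng.standard_normal((40, 5)), columns=list("abcde"))
        y = rng.standard_normal(40)
        res = adjust_fixed_effects(y, cov)
        X = build_design(cov)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(res, y - X @ beta, atol=1e-10)

    def test_collinear_columns_named(self):
        cov = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(InputError, match="b"):
            adjust_fixed_effects(np.arange(4.0), cov)


class TestRemlFit:
    def test_constant_response_rejected(self):
        K = family_kernel()
        with pytest.raises(InputError, match="variance"):
            fit_reml_lmm(np.ones(8), K)

    @pytest.mark.parametrize("seed,within", [(10, 0.5), (11, 0.5), (12, 0.8)])
    def test_matches_exhaustive_grid_search(self, seed, within):
        """Engine optimum equals a 1e-4-resolution grid scan within 1e-3."""
        K = family_kernel(within=within)
        y = _frozen_y(seed)
        fit = fit_reml_lmm(y, K)
        r_grid = oracle_grid_ratio(y, K.values)
        assert fit.ratio == pytest.approx(r_grid, abs=1e-3)

    def test_loglik_matches_direct_mvn_evaluation(self):
        """Fixed-component log-likelihood equals an independent MVN logpdf."""
        K = family_kernel()
        y = _frozen_y(13)
        for su2, se2 in [(1.0, 1.0), (0.3, 0.9), (2.0, 0.5)]:
            got = reml_loglik(y, K, su2, se2)
            U2 = linalg.null_space(np.ones((1, 8)))
            cov = U2.T @ (su2 * K.values + se2 * np.eye(8)) @ U2
            expected = stats.multivariate_normal.logpdf(U2.T @ y, cov=cov)
            assert got == pytest.approx(expected, abs=1e-8)

    def test_scale_equivariance(self):
        K = family_kernel(n_families=5, family_size=4)
        rng = np.random.default_rng(2)
        y = rng.standard_normal(20)
        f1 = fit_reml_lmm(y, K)
        f2 = fit_reml_lmm(3.7 * y, K)
        assert f2.ratio == pytest.approx(f1.ratio, abs=1e-6)
        assert f2.sigma_u2 == pytest.approx(3.7**2 * f1.sigma_u2, rel=1e-4)
        assert f2.sigma_e2 == pytest.approx(3.7**2 * f1.sigma_e2, rel=1e-4)

    def test_kernel_rotation_identity(self):
        """Fitting P K P' with permuted y reproduces the fit exactly."""
        from holoherit.genomics import RelationshipMatrix

        K = family_kernel(n_families=4, family_size=3)
        rng = np.random.default_rng(3)
        y = rng.standard_normal(12)
        perm = rng.permutation(12)
        Kp = RelationshipMatrix(
            K.values[np.ix_(perm, perm)], [K.sample_ids[i] for i in perm]
        )
        f1 = fit_reml_lmm(y, K)
        f2 = fit_reml_lmm(y[perm], Kp)
        assert f2.ratio == pytest.approx(f1.ratio, abs=1e-9)
        assert f2.loglik_reml == pytest.approx(f1.loglik_reml, abs=1e-9)

    def test_ratio_identity_holds(self):
        K = family_kernel(n_families=6, family_size=4)
        y = np.random.default_rng(4).standard_normal(24)
        fit = fit_reml_lmm(y, K)
        assert fit.ratio == pytest.approx(
            fit.sigma_u2 / (fit.sigma_u2 + fit.sigma_e2), abs=1e-10
        )
        assert 0 <= fit.p_value <= 1

    def test_fixed_effects_inside_model(self):
        """A strong fixed effect left in y inflates nothing once modelled."""
        K = family_kernel(n_families=10, family_size=4)
        rng = np.random.default_rng(5)
        x = rng.standard_normal(40)
        y = 5.0 * x + rng.standard_normal(40)
        fixed = pd.DataFrame({"x": x}, index=K.sample_ids)
        fit = fit_reml_lmm(y, K, fixed=fixed)
        assert fit.ratio < 0.6  # no spurious kernel variance from the covariate

    def test_null_calibration(self):
        """y ~ N(0, I): heritable calls stay at or below 10% of 200 fits."""
        K = family_kernel(n_families=15, family_size=4, within=0.5)
        ws = RemlWorkspace(K)
        rng = np.random.default_rng(6)
        calls = 0
        for _ in range(200):
            fit = ws.fit(rng.standard_normal(60))
            status, _ = classify_heritable(fit)
            calls += status == "heritable"
        assert calls / 200 <= 0.10


class TestClassification:
    @pytest.mark.parametrize(
        "ratio,se,p,status,category",
        [
            (0.5, 0.1, 0.001, "heritable", "high"),
            (0.5, 0.3, 0.001, "nonheritable", ""),
            (0.3, 0.1, 0.01, "heritable", "moderate"),
            (0.15, 0.05, 0.01, "heritable", "low"),
            (0.5, 0.1, 0.2, "nonheritable", ""),
            (0.4, 0.1, 0.001, "heritable", "moderate"),  # 0.4 is not "high"
        ],
    )
    def test_rules(self, ratio, se, p, status, category):
        fit = VarCompFit(ratio, 1 - ratio, ratio, se, 0.0, p, True, 100)
        assert classify_heritable(fit) == (status, category)

    def test_nonconverged_refused(self):
        fit = VarCompFit(0.5, 0.5, 0.5, 0.1, 0.0, 0.001, False, 100)
        with pytest.raises(InputError, match="converge"):
            classify_heritable(fit)
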