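"""Core estimator checks: gradients, implied moments, parameter counting,
self-consistency, invariances and the fit-index closed forms."""

import numpy as np
import pytest

from panelgvar import engine


def _random_model(p, seed, rho=0.4):
    rng = np.random.default_rng(seed)
    B = rng.normal(0, 0.3, (p, p))
    r = engine.spectral_radius(B)
    if r >= rho:
        B *= rho / r
    A = rng.normal(0, 0.4, (p, p))
    sigma_z = A @ A.T + 0.5 * np.eye(p)
    C = rng.normal(0, 0.3, (p, p))
    sigma_b = C @ C.T + 0.2 * np.eye(p)
    mu = rng.normal(0, 1, p)
    return B, sigma_z, sigma_b, mu


class TestImpliedMoments:
    def test_identity_case(self):
        p, T = 3, 4
        mean, Sigma = engine.implied_moments(
            np.zeros((p, p)), np.eye(p), np.zeros((p, p)), np.zeros(p), T
        )
        assert np.allclose(Sigma, np.eye(p * T))
        assert np.allclose(mean, 0.0)

    def test_pure_random_intercept(self):
        p, T = 3, 4
        rng = np.random.default_rng(1)
        A = rng.normal(0, 0.5, (p, p))
        Sb = A @ A.T + 0.1 * np.eye(p)
        _, Sigma = engine.implied_moments(
            np.zeros((p, p)), np.eye(p), Sb, np.zeros(p), T
        )
        for t in range(T):
            for s in range(T):
                blk = Sigma[t * p:(t + 1) * p, s * p:(s + 1) * p]
                expected = Sb + (np.eye(p) if t == s else 0.0)
                assert np.allclose(blk, expected)

    def test_nonstationary_rejected(self):
        p = 2
        B = np.eye(p) * 1.05
        with pytest.raises(ValueError, match="non-stationary"):
            engine.stationary_within_cov(B, np.eye(p))

    def test_lyapunov_identity(self):
        B, sz, _, _ = _random_model(4, 7)
        S0 = engine.stationary_within_cov(B, sz)
        assert np.allclose(S0, B @ S0 @ B.T + sz, atol=1e-10)


def test_analytic_gradient_matches_finite_differences():
    p, T = 3, 4
    B, sz, sb, mu = _random_model(p, 3)
    m0, S = engine.implied_moments(*_random_model(p, 4), T)
    S = S + 0.05 * np.eye(p * T)
    mbar = m0 + 0.1
    lds = np.linalg.slogdet(S)[1]

    F, (gB, gSz, gSb, gmu) = engine.discrepancy(S, mbar, B, sz, sb, mu, T, lds)
    eps = 1e-6

    def num_grad(wrap, x):
        g = np.zeros_like(x, dtype=float)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            xp = x.copy()
            xp[idx] += eps
            xm = x.copy()
            xm[idx] -= eps
            g[idx] = (wrap(xp) - wrap(xm)) / (2 * eps)
        return g

    def f_only(B_, sz_, sb_, mu_):
        return engine.discrepancy(
            S, mbar, B_, 0.5 * (sz_ + sz_.T), 0.5 * (sb_ + sb_.T), mu_, T,
            lds, with_grad=False,
        )

    assert np.abs(num_grad(lambda x: f_only(x, sz, sb, mu), B) - gB).max() < 1e-6
    gSz_n = num_grad(lambda x: f_only(B, x, sb, mu), sz)
    assert np.abs(0.5 * (gSz_n + gSz_n.T) - gSz).max() < 1e-6
    assert np.abs(num_grad(lambda x: f_only(B, sz, x, mu), sb) - gSb).max() < 1e-6
    assert np.abs(num_grad(lambda x: f_only(B, sz, sb, x), mu) - gmu).max() < 1e-6


class TestParameterCounting:
    @pytest.mark.parametrize("p", range(2, 26))
    @pytest.mark.parametrize("T", range(2, 9))
    def test_df_formula_equals_enumeration(self, p, T):
        # enumerate free parameters and distinct moments one by one
        n_params = 0
        for _ in range(p):
            for _ in range(p):
                n_params += 1                      # temporal coefficients
        for i in range(p):
            for _ in range(i + 1):
                n_params += 2                      # two symmetric precisions
        n_params += p                              # stationary means
        pt = p * T
        n_moments = pt                             # means
        for i in range(pt):
            for _ in range(i + 1):
                n_moments += 1                     # covariance entries
        assert engine.saturated_df(p, T) == n_moments - n_params


class TestFitML:
    def test_population_moments_self_consistency(self):
        p, T = 4, 5
        B, sz, sb, mu = _random_model(p, 11, rho=0.5)
        mean, Sigma = engine.implied_moments(B, sz, sb, mu, T)
        fit = engine.fit_ml(Sigma, mean, p, T)
        assert fit.converged
        assert fit.discrepancy < 1e-8
        assert np.abs(fit.B - B).max() < 1e-4
        assert np.abs(fit.sigma_zeta - sz).max() < 1e-4
        assert np.abs(fit.sigma_between - sb).max() < 1e-4
        assert np.abs(fit.mu - mu).max() < 1e-6

    def test_discrepancy_nonnegative_zero_iff_exact(self):
        p, T = 3, 4
        B, sz, sb, mu = _random_model(p, 12)
        mean, Sigma = engine.implied_moments(B, sz, sb, mu, T)
        lds = np.linalg.slogdet(Sigma)[1]
        F0 = engine.discrepancy(
            Sigma, mean, B, sz, sb, mu, T, lds, with_grad=False
        )
        assert abs(F0) < 1e-10
        F1 = engine.discrepancy(
            Sigma + 0.1 * np.eye(p * T), mean, B, sz, sb, mu, T,
            np.linalg.slogdet(Sigma + 0.1 * np.eye(p * T))[1],
            with_grad=False,
        )
        assert F1 > 0

    def test_fit_equivariant_to_feature_permutation(self):
        p, T = 3, 4
        B, sz, sb, mu = _random_model(p, 13, rho=0.5)
        mean, Sigma = engine.implied_moments(B, sz, sb, mu, T)
        # noise-perturb so the optimum is not the generating model exactly
        rng = np.random.default_rng(0)
        E = rng.normal(0, 0.01, Sigma.shape)
        Sigma = Sigma + E @ E.T
        fit = engine.fit_ml(Sigma, mean, p, T)

        perm = np.array([2, 0, 1])
        idx = np.concatenate([t * p + perm for t in range(T)])
        fit_p = engine.fit_ml(Sigma[np.ix_(idx, idx)], mean[idx], p, T)
        assert np.abs(fit_p.B - fit.B[np.ix_(perm, perm)]).max() < 1e-4
        assert np.abs(
            fit_p.omega_zeta - fit.omega_zeta[np.ix_(perm, perm)]
        ).max() < 1e-4
        assert np.abs(fit_p.mu - fit.mu[perm]).max() < 1e-5

    def test_sparse_refit_never_beats_saturated(self):
        p, T = 3, 4
        B, sz, sb, mu = _random_model(p, 14, rho=0.5)
        mean, Sigma = engine.implied_moments(B, sz, sb, mu, T)
        rng = np.random.default_rng(2)
        E = rng.normal(0, 0.02, Sigma.shape)
        Sigma = Sigma + E @ E.T
        sat = engine.fit_ml(Sigma, mean, p, T)
        mask_B = np.ones((p, p), dtype=bool)
        mask_B[0, 1] = False
        sparse = engine.fit_ml_masked(
            Sigma, mean, p, T, start=sat, mask_B=mask_B
        )
        assert sparse.B[0, 1] == 0.0
        assert sparse.discrepancy >= sat.discrepancy - 1e-10


class TestFitIndices:
    def test_perfect_fit_boundary(self):
        fi = engine.fit_indices(100.0, 100, 500, 2000.0, 120)
        assert fi.rmsea == 0.0
        assert fi.cfi == 1.0

    def test_tli_zero_when_ratios_match(self):
        fi = engine.fit_indices(200.0, 100, 500, 240.0, 120)
        assert fi.tli == pytest.approx(0.0)

    def test_rmsea_from_printed_statistics(self):
        # chi2 = 14455 on 8625 df with n = 6462 gives RMSEA ~ 0.0102
        fi = engine.fit_indices(14455.0, 8625, 6462, 150000.0, 9453)
        assert fi.rmsea == pytest.approx(0.0102, abs=2e-4)
        lo, hi = fi.rmsea_ci
        assert lo == pytest.approx(0.0099, abs=3e-4)
        assert hi == pytest.approx(0.011, abs=5e-4)

    def test_rmsea_ci_brackets_estimate(self):
        fi = engine.fit_indices(180.0, 100, 400, 900.0, 120)
        lo, hi = fi.rmsea_ci
        assert lo <= fi.rmsea <= hi

    def test_baseline_chi2_identity_correlation(self):
        # uncorrelated sample covariance -> baseline chi2 = 0
        S = np.diag([1.0, 2.0, 3.0])
        chi2, df = engine.baseline_chi2(S, 100)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert df == 3
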