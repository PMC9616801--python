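"""Decay fits, lag profiles, permutation machinery, correlation profiles."""

import numpy as np
import pytest

from commdyn.dynamics import (
    fit_decay,
    initial_slope,
    lag_profile,
    pairwise_noise_correlations,
    permutation_test_tau,
    spike_autocorrelation,
)


class TestLagProfile:
    def test_mean_over_diagonals(self):
        m = np.arange(16).reshape(4, 4).astype(float)
        prof = lag_profile(m)
        assert prof[0] == pytest.approx(np.mean([0, 5, 10, 15]))
        assert prof[3] == pytest.approx(3.0)

    @pytest.mark.parametrize("profile,expected", [([0.8, 0.6], -0.2), ([0.5, 0.5, 0.5], 0.0)])
    def test_initial_slope(self, profile, expected):
        assert initial_slope(np.array(profile)) == pytest.approx(expected)

    def test_initial_slope_needs_two_lags(self):
        with pytest.raises(ValueError):
            initial_slope(np.array([0.7]))


class TestFitDecay:
    def test_noiseless_recovery(self):
        t = np.arange(8) * 65.0
        y = 1.0 * (np.exp(-t / 100.0) + 0.2)
        f = fit_decay(t, y, n_boot=0)
        assert f.converged
        np.testing.assert_allclose([f.A, f.tau, f.B], [1.0, 100.0, 0.2], rtol=1e-5)

    def test_profile_and_trf_methods_agree(self):
        rng = np.random.default_rng(0)
        t = np.arange(8) * 66.0
        y = 0.7 * (np.exp(-t / 150.0) + 0.3) + rng.normal(0, 0.03, 8)
        f1 = fit_decay(t, y, n_boot=0, method="profile")
        f2 = fit_decay(t, y, n_boot=0, method="trf")
        np.testing.assert_allclose([f1.A, f1.tau, f1.B], [f2.A, f2.tau, f2.B], rtol=1e-3)

    def test_constant_profile_flagged_degenerate(self):
        t = np.arange(8) * 66.0
        f = fit_decay(t, np.full(8, 0.6), n_boot=0)
        assert f.degenerate
        assert not f.converged

    def test_flat_noisy_profile_resolves_to_slow_bound(self):
        rng = np.random.default_rng(1)
        t = np.arange(8) * 66.0
        taus = [fit_decay(t, 0.6 + rng.normal(0, 0.02, 8), n_boot=0).tau for _ in range(20)]
        assert np.mean(np.array(taus) > 5e3) > 0.9

    def test_near_linear_limit_matches_regression(self):
        # tau >> t: y ~ A(1+B) - A t / tau, slope -A/tau
        t = np.arange(8) * 66.0
        A, tau, B = 2.0, 8000.0, 0.1
        y = A * (np.exp(-t / tau) + B)
        coef = np.polyfit(t, y, 1)
        assert coef[0] == pytest.approx(-A / tau, rel=0.03)

    def test_bootstrap_ci_contains_point_estimate(self):
        rng = np.random.default_rng(2)
        t = np.arange(8) * 66.0
        y = 0.8 * (np.exp(-t / 120.0) + 0.25)[None, :] + rng.normal(0, 0.05, (10, 8))
        f = fit_decay(t, y, n_boot=100, seed=3)
        lo, hi = f.ci["tau"]
        assert lo <= f.tau <= hi

    def test_too_few_lags_raises(self):
        with pytest.raises(ValueError):
            fit_decay(np.array([0, 66, 132.0]), np.array([1.0, 0.5, 0.4]))


class TestPermutationTest:
    def test_n_perm_guard(self):
        rng = np.random.default_rng(0)
        ctrl = rng.poisson(3.0, (8, 20, 4)).astype(float)
        sil = [rng.poisson(3.0, (12, 4)).astype(float) for _ in range(8)]
        cg = np.array([True, False] * 10)
        sg = [np.array([True, False] * 6) for _ in range(8)]
        with pytest.raises(ValueError):
            permutation_test_tau(ctrl, cg, sil, sg, gamma=0.5, n_perm=0)

    def test_p_value_bounds_and_reproducibility(self):
        rng = np.random.default_rng(1)
        ctrl = rng.poisson(3.0, (8, 24, 6)).astype(float)
        sil = [rng.poisson(2.0, (16, 6)).astype(float) for _ in range(8)]
        cg = np.array([True, False] * 12)
        sg = [np.array([True, False] * 8) for _ in range(8)]
        r1 = permutation_test_tau(ctrl, cg, sil, sg, gamma=0.5, n_perm=30, seed=5)
        r2 = permutation_test_tau(ctrl, cg, sil, sg, gamma=0.5, n_perm=30, seed=5)
        assert 1 / 31 <= r1.p_value <= 1.0
        assert r1.p_value == r2.p_value
        assert r1.observed_delta_tau == r2.observed_delta_tau


class TestAutocorrelation:
    def test_trial_constant_rate_profile_uncorrelated(self):
        # deterministic rate + Poisson emission: zero across-trial covariance
        rng = np.random.default_rng(0)
        lam = np.linspace(2, 6, 7)  # strong envelope, identical across trials
        counts = rng.poisson(lam, (4000, 7))
        lags, r, used = spike_autocorrelation(counts)
        assert r[0] == pytest.approx(1.0)
        assert np.abs(r[1:]).max() < 0.05

    def test_identical_bins_fully_correlated(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(5.0, (200, 1))
        counts = np.tile(col, (1, 5))
        lags, r, used = spike_autocorrelation(counts)
        np.testing.assert_allclose(r, 1.0, atol=1e-12)

    def test_ar1_modulated_rates_match_total_covariance_oracle(self):
        # lognormal AR(1) log-rate: Cov(N_t, N_t+k) = lam^2 (exp(s^2 rho^k) - 1)
        rng = np.random.default_rng(2)
        n_tr, n_bins, lam0, s, rho = 20000, 7, 5.0, 0.35, 0.6
        g = np.zeros((n_tr, n_bins))
        g[:, 0] = rng.standard_normal(n_tr)
        for b in range(1, n_bins):
            g[:, b] = rho * g[:, b - 1] + np.sqrt(1 - rho**2) * rng.standard_normal(n_tr)
        lam = lam0 * np.exp(s * g - s * s / 2)
        counts = rng.poisson(lam)
        lags, r, used = spike_autocorrelation(counts)
        var = lam0 + lam0**2 * (np.exp(s * s) - 1)
        expect = np.array(
            [1.0] + [lam0**2 * (np.exp(s * s * rho**k) - 1) / var for k in range(1, n_bins)]
        )
        np.testing.assert_allclose(r, expect, atol=0.03)


class TestNoiseCorrelations:
    def test_independent_neurons_near_zero(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(4.0, (3000, 3, 6))
        nc = pairwise_noise_correlations(counts)
        assert abs(np.mean(nc["r"])) < 0.01

    def test_no_self_pairs_and_mean_count_column(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(4.0, (100, 2, 4))
        nc = pairwise_noise_correlations(counts)
        assert np.all(nc["i"] < nc["j"])
        assert nc["mean_count"].min() > 0

    def test_shared_latent_factor_matches_oracle(self):
        # two neurons driven by one lognormal factor with loadings s each:
        # Cov = lam^2 (e^{s^2} - 1); Var = lam + lam^2 (e^{s^2} - 1)
        rng = np.random.default_rng(5)
        n_tr, lam0, s = 40000, 5.0, 0.3
        z = rng.standard_normal(n_tr)
        lam = lam0 * np.exp(s * z[:, None] - s * s / 2)
        counts = rng.poisson(np.repeat(lam, 2, axis=1))[:, None, :]
        nc = pairwise_noise_correlations(counts)
        cov = lam0**2 * (np.exp(s * s) - 1)
        var = lam0 + cov
        assert nc["r"][0] == pytest.approx(cov / var, abs=0.02)
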