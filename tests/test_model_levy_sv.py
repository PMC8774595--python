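"""Tempered-stable OU volatility model: series sampler, recursion, simulator."""

import numpy as np
import pytest
from scipy.special import gamma as gamma_fn

from repmmh import _sv_kernels
from repmmh.model_levy_sv import (IncrementDraw, LevySVModel, SVParams,
                                  TRUE_PARAMS, latent_step, log_obs_density,
                                  sample_increments, simulate_dataset,
                                  tempered_stable_constant)

STUDY = SVParams(*TRUE_PARAMS)  # kappa=0.5, delta=1.41, gamma=2.83, lam=0.1


def _batch(params, eps, n, seed):
    A = tempered_stable_constant(params.kappa, params.delta)
    return _sv_kernels.sample_eta_batch(params.kappa, params.delta, params.gamma,
                                        params.lam, params.Delta, A, eps, n, seed)


class TestTemperedStableConstant:
    def test_half_stable_value(self):
        # kappa=1/2, delta=1: sqrt(2)*0.5/Gamma(0.5) = sqrt(2)/(2 sqrt(pi))
        assert tempered_stable_constant(0.5, 1.0) == pytest.approx(
            np.sqrt(2.0) / (2.0 * np.sqrt(np.pi)), rel=1e-12)
        assert tempered_stable_constant(0.5, 1.0) == pytest.approx(0.39894, abs=5e-6)

    def test_linear_in_delta(self):
        assert tempered_stable_constant(0.3, 2.0) == pytest.approx(
            2.0 * tempered_stable_constant(0.3, 1.0), rel=1e-12)

    @pytest.mark.parametrize("kappa", [0.05, 0.5, 0.95])
    def test_positive_on_domain(self, kappa):
        assert tempered_stable_constant(kappa, 0.7) > 0.0

    def test_domain_violations_raise(self):
        with pytest.raises(ValueError):
            tempered_stable_constant(1.0, 1.0)
        with pytest.raises(ValueError):
            tempered_stable_constant(0.5, 0.0)


class TestSampleIncrements:
    def test_eta_ordering_never_violated(self):
        eta_s, eta_z, _, _ = _batch(STUDY, 1e-6, 100_000, seed=12)
        assert np.all(eta_s >= 0.0)
        assert np.all(eta_s <= eta_z)

    def test_compound_poisson_count_mean(self):
        # mean lam*Delta*delta*gamma*kappa = 0.1*1.41*2.83*0.5 = 0.199515
        expected = 0.1 * 1.41 * 2.83 * 0.5
        assert expected == pytest.approx(0.19953, abs=5e-5)
        _, _, _, jumps = _batch(STUDY, 1e-5, 40_000, seed=13)
        se = np.sqrt(expected / jumps.size)  # Poisson variance = mean
        assert abs(jumps.mean() - expected) < 3 * se

    def test_truncation_convergence_of_eta_z_mean(self):
        # halving the threshold changes the mean of eta_z by far less than 1%
        m = {}
        for eps in (1e-6, 5e-7):
            _, eta_z, _, _ = _batch(STUDY, eps, 20_000, seed=14)
            m[eps] = eta_z.mean()
        assert abs(m[5e-7] - m[1e-6]) / m[1e-6] < 0.01

    def test_single_draw_wrapper_and_validation(self):
        draw = sample_increments(STUDY, np.random.default_rng(0), 1e-6)
        assert isinstance(draw, IncrementDraw)
        assert 0.0 <= draw.eta_sigma <= draw.eta_z
        assert draw.terms_used >= 1
        with pytest.raises(ValueError):
            sample_increments(STUDY, np.random.default_rng(0), -1.0)

    def test_truncation_length_scales_with_threshold(self):
        _, _, terms6, _ = _batch(STUDY, 1e-6, 2_000, seed=15)
        _, _, terms8, _ = _batch(STUDY, 1e-8, 2_000, seed=15)
        # expected terms ~ eps^-kappa: 100x smaller eps -> 10x terms at kappa=0.5
        assert 8 < terms8.mean() / terms6.mean() < 12


class TestLatentStep:
    def test_hand_evaluated_decay_without_increments(self):
        zero = IncrementDraw(0.0, 0.0, 1, 0)
        s_new, z_new, integ = latent_step(2.0, 5.0, zero, STUDY)
        assert s_new == pytest.approx(2.0 * np.exp(-0.1), rel=1e-12)
        assert s_new == pytest.approx(1.80967, abs=5e-6)
        assert integ == pytest.approx(10.0 * (2.0 - 2.0 * np.exp(-0.1)), rel=1e-12)
        assert integ == pytest.approx(1.90325, abs=5e-6)
        assert z_new == 5.0

    def test_vanishing_mean_reversion_freezes_sigma2(self):
        params = SVParams(0.5, 1.41, 2.83, 1e-12)
        zero = IncrementDraw(0.0, 0.0, 1, 0)
        s_new, _, _ = latent_step(2.0, 0.0, zero, params)
        assert s_new == pytest.approx(2.0, rel=1e-9)

    def test_z_nondecreasing_over_draws(self):
        rng = np.random.default_rng(3)
        sigma2, z = 1.0, 0.0
        for _ in range(300):
            draw = sample_increments(STUDY, rng, 1e-6)
            sigma2, z_new, integ = latent_step(sigma2, z, draw, STUDY)
            assert z_new >= z
            assert integ >= 0.0
            z = z_new


class TestObservationDensity:
    def test_standard_normal_case(self):
        params = SVParams(0.5, 1.41, 2.83, 0.1, mu=0.0, beta=0.0)
        assert log_obs_density(0.0, 1.0, params) == pytest.approx(
            -0.5 * np.log(2 * np.pi))

    def test_mean_includes_drift_and_risk_premium(self):
        params = SVParams(0.5, 1.41, 2.83, 0.1, mu=1.0, beta=2.0, Delta=1.0)
        # mean = mu*Delta + beta*vol = 7; density maximal at y = 7
        assert log_obs_density(7.0, 3.0, params) > log_obs_density(6.0, 3.0, params)

    def test_zero_volatility_kills_particle(self):
        assert log_obs_density(0.5, 0.0, STUDY) == -np.inf


class TestSimulateDataset:
    def test_integrated_volatility_positive_and_reproducible(self):
        latent1, ts1 = simulate_dataset(STUDY, 200, np.random.default_rng(6),
                                        epsilon_trunc=1e-6)
        latent2, ts2 = simulate_dataset(STUDY, 200, np.random.default_rng(6),
                                        epsilon_trunc=1e-6)
        assert np.all(latent1[:, 1] >= 0.0)
        np.testing.assert_array_equal(ts1.observations, ts2.observations)
        np.testing.assert_array_equal(latent1, latent2)

    def test_zero_drift_returns_have_zero_mean(self):
        _, ts = simulate_dataset(STUDY, 10_000, np.random.default_rng(7),
                                 epsilon_trunc=1e-6)
        y = ts.observations
        se = y.std(ddof=1) / np.sqrt(y.size)
        assert abs(y.mean()) < 3 * se

    def test_sigma2_lag1_autocorrelation_matches_ou_decay(self):
        # exact discretization: corr(sigma2_n, sigma2_{n-1}) = exp(-lam*Delta)
        latent, _ = simulate_dataset(STUDY, 20_000, np.random.default_rng(8),
                                     epsilon_trunc=1e-6)
        s = latent[2_000:, 0]  # discard transient from sigma2_init
        sc = s - s.mean()
        rho1 = float(sc[:-1] @ sc[1:]) / float(sc @ sc)
        assert rho1 == pytest.approx(np.exp(-0.1), abs=0.03)


class TestFilterContract:
    def test_generic_filter_runs_and_is_finite(self):
        model = LevySVModel(STUDY, epsilon_trunc=1e-6, use_fast_filter=False)
        _, ts = simulate_dataset(STUDY, 30, np.random.default_rng(10),
                                 epsilon_trunc=1e-6)
        from repmmh.smc import run_filter

        theta = model.make_theta(TRUE_PARAMS)
        res = run_filter(model, theta, ts, M=30, rng=np.random.default_rng(11))
        assert np.isfinite(res.log_marginal_likelihood)

    def test_fast_and_generic_agree_statistically(self):
        model = LevySVModel(STUDY, epsilon_trunc=1e-6)
        _, ts = simulate_dataset(STUDY, 25, np.random.default_rng(12),
                                 epsilon_trunc=1e-6)
        theta = model.make_theta(TRUE_PARAMS)
        fast = np.array([model.fast_loglik(theta.values, ts, 40, 300 + i)
                         for i in range(150)])
        from repmmh.smc import run_filter

        gen = np.array([run_filter(model, theta, ts, 40,
                                   np.random.default_rng(600 + i)
                                   ).log_marginal_likelihood for i in range(60)])
        se = np.sqrt(fast.var(ddof=1) / fast.size + gen.var(ddof=1) / gen.size)
        assert abs(fast.mean() - gen.mean()) < 3 * se

    def test_parameter_transforms_declared_for_positivity(self):
        model = LevySVModel()
        assert model.param_transforms == ("logit", "log", "log", "log")
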