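"""Likelihoods, AICc selection, and rate recovery for the two mean models."""

import numpy as np
import pytest

from loxkit.rate_inference import (ExponentialParams, LogisticParams, aicc,
                                   ensemble_summary, fit_exponential,
                                   fit_logistic_mcmc, loglik, observed_f0,
                                   select_model)
from loxkit.synthetic_data import (SwitchingTrajectory,
                                   eval_logistic_fraction)


def _count_traj(times, x, n):
    x = np.asarray(x, dtype=np.int64)
    n = np.broadcast_to(np.asarray(n, dtype=np.int64), x.shape)
    return SwitchingTrajectory(times=np.asarray(times, dtype=float),
                               fractions=x / n, counts=(x, n))


def _logistic_counts(k, fmax, f0, t, n_events, seed):
    rng = np.random.default_rng(seed)
    f = eval_logistic_fraction(t, f0, fmax, k)
    x = rng.binomial(n_events, f)
    return _count_traj(t, x, n_events)


class TestLoglik:
    def test_binomial_kernel_hand_value(self):
        traj = _count_traj([0.0], [5], [10])
        ll = loglik(traj, "exponential", ExponentialParams(f0=0.5, k=0.0))
        assert ll == pytest.approx(10 * np.log(0.5))

    def test_perfect_prediction_is_maximum(self):
        traj = _count_traj([0.0], [30], [100])
        best = loglik(traj, "exponential", ExponentialParams(f0=0.3, k=0.0))
        for p in (0.25, 0.28, 0.32, 0.4):
            assert loglik(traj, "exponential",
                          ExponentialParams(f0=p, k=0.0)) < best

    def test_doubling_counts_doubles_kernel(self):
        t = [0.0, 2.0, 4.0]
        a = _count_traj(t, [10, 20, 40], [1000, 1000, 1000])
        b = _count_traj(t, [20, 40, 80], [2000, 2000, 2000])
        params = ExponentialParams(f0=0.01, k=0.3)
        assert loglik(b, "exponential", params) == pytest.approx(
            2 * loglik(a, "exponential", params))

    def test_discordant_degenerate_prediction_is_minus_inf(self):
        traj = _count_traj([0.0, 10.0], [10, 999], [1000, 1000])
        # k large enough that the exponential prediction exceeds 1 at t=10
        ll = loglik(traj, "exponential", ExponentialParams(f0=0.01, k=1.0))
        assert ll == -np.inf

    def test_gaussian_fallback_requires_n(self):
        traj = SwitchingTrajectory(times=np.array([0.0, 1.0]),
                                   fractions=np.array([0.01, 0.02]))
        with pytest.raises(ValueError, match="n_events"):
            loglik(traj, "exponential", ExponentialParams(f0=0.01, k=0.5))
        ll = loglik(traj, "exponential", ExponentialParams(f0=0.01, k=0.5),
                    n_events=1e4)
        assert np.isfinite(ll)


class TestAicc:
    def test_hand_value(self):
        assert aicc(-10.0, 2, 8) == pytest.approx(26.4)

    def test_penalty_prefers_fewer_params_at_equal_likelihood(self):
        assert aicc(-10.0, 1, 8) < aicc(-10.0, 2, 8)

    def test_reduces_to_aic_for_large_n(self):
        aic = -2 * (-10.0) + 2 * 2
        assert aicc(-10.0, 2, 10**7) == pytest.approx(aic, abs=1e-5)

    def test_undefined_for_tiny_n(self):
        with pytest.raises(ValueError, match="n_obs"):
            aicc(-10.0, 2, 3)


class TestFitExponential:
    def test_noiseless_recovery(self):
        t = np.linspace(0, 8, 7)
        f0, k = 0.001, 0.3
        traj = SwitchingTrajectory(times=t, fractions=f0 * np.exp(k * t))
        fit = fit_exponential(traj, n_events=1e6)
        assert fit.k == pytest.approx(k, abs=1e-6)

    def test_two_point_closed_form(self):
        f0, f1, t1 = 0.002, 0.016, 4.0
        traj = SwitchingTrajectory(times=np.array([0.0, t1]),
                                   fractions=np.array([f0, f1]))
        fit = fit_exponential(traj, n_events=1e5)
        assert fit.k == pytest.approx(np.log(f1 / f0) / t1, abs=1e-6)

    def test_constant_data_boundary_optimum(self):
        traj = _count_traj(np.linspace(0, 8, 7), [20] * 7, 20_000)
        fit = fit_exponential(traj)
        assert fit.k == pytest.approx(0.0, abs=1e-9)

    def test_zero_inducer_rate_near_zero(self):
        # leak-free synthetic data: k_hat within ~3 likelihood-se of 0
        traj = _logistic_counts(0.0, 0.9, 0.001, np.linspace(0, 8, 7),
                                20_000, seed=5)
        fit = fit_exponential(traj)
        assert 0.0 <= fit.k < 0.055


class TestFitLogisticMcmc:
    def test_recovers_rate_in_weakly_saturating_regime(self):
        t = np.linspace(0, 8, 7)
        traj = _logistic_counts(0.6, 0.8, 0.001, t, 100_000, seed=2)
        fit = fit_logistic_mcmc(traj, seed=2)
        assert fit.converged
        assert fit.k == pytest.approx(0.6, rel=0.10)
        assert fit.params["fmax"] >= traj.fractions.max()

    def test_recovers_fmax_when_saturation_visible(self):
        t = np.linspace(0, 10, 9)
        traj = _logistic_counts(1.0, 0.8, 0.001, t, 100_000, seed=3)
        fit = fit_logistic_mcmc(traj, seed=3)
        assert fit.params["fmax"] == pytest.approx(0.8, abs=0.05)
        assert fit.k == pytest.approx(1.0, rel=0.10)

    def test_flat_trajectory_flagged_non_identifiable(self):
        traj = _count_traj(np.linspace(0, 8, 7), [20] * 7, 20_000)
        fit = fit_logistic_mcmc(traj, seed=1)
        assert not fit.identifiable

    def test_empty_fmax_bound_collapses_to_one_parameter(self):
        t = np.linspace(0, 8, 5)
        f = eval_logistic_fraction(t, 0.05, 1.0, 1.5)
        n = np.full(t.size, 1000)
        x = np.round(f * n).astype(np.int64)
        x[-1] = n[-1]  # max measured fraction = 1
        traj = _count_traj(t, x, n)
        fit = fit_logistic_mcmc(traj, seed=1)
        assert fit.params["fmax"] == 1.0 and fit.n_params == 1

    def test_matches_exponential_far_from_saturation(self):
        t = np.linspace(0, 8, 7)
        traj = _logistic_counts(0.3, 0.9, 0.001, t, 100_000, seed=4)
        exp_fit = fit_exponential(traj)
        log_fit = fit_logistic_mcmc(traj, seed=4)
        assert log_fit.k == pytest.approx(exp_fit.k, rel=0.05)

    def test_seeded_runs_identical(self):
        traj = _logistic_counts(0.6, 0.8, 0.001, np.linspace(0, 8, 7),
                                20_000, seed=6)
        a = fit_logistic_mcmc(traj, seed=9)
        b = fit_logistic_mcmc(traj, seed=9)
        assert a.params == b.params and a.max_loglik == b.max_loglik


class TestSelectModel:
    def _fits(self, aicc_exp, aicc_log):
        exp_fit = fit_exponential(_logistic_counts(
            0.2, 0.9, 0.001, np.linspace(0, 8, 7), 10_000, seed=1))
        log_fit = fit_logistic_mcmc(_logistic_counts(
            0.2, 0.9, 0.001, np.linspace(0, 8, 7), 10_000, seed=1),
            seed=1, n_steps=400, n_burn=100)
        exp_fit.aicc, log_fit.aicc = aicc_exp, aicc_log
        return exp_fit, log_fit

    def test_zero_concentration_forces_exponential(self):
        exp_fit, log_fit = self._fits(26.0, 20.0)
        assert select_model(exp_fit, log_fit, 0.0) is exp_fit
        assert select_model(exp_fit, None, 0.0) is exp_fit

    def test_argmin_aicc(self):
        exp_fit, log_fit = self._fits(26.0, 20.0)
        assert select_model(exp_fit, log_fit, 1e-6) is log_fit
        exp_fit.aicc, log_fit.aicc = 20.0, 26.0
        assert select_model(exp_fit, log_fit, 1e-6) is exp_fit

    def test_tie_goes_to_fewer_parameters(self):
        exp_fit, log_fit = self._fits(20.0, 20.0)
        assert select_model(exp_fit, log_fit, 1e-6) is exp_fit


class TestEnsembleSummary:
    def test_single_replicate_degenerate_envelope(self):
        traj = _logistic_counts(0.4, 0.9, 0.001, np.linspace(0, 8, 7),
                                50_000, seed=7)
        fit = fit_exponential(traj)
        ens = ensemble_summary([fit], np.linspace(0, 8, 17))
        assert np.allclose(ens.mean_curve, ens.min_curve)
        assert ens.k_min == ens.k_mean == ens.k_max == fit.k

    def test_two_replicate_arithmetic(self):
        from loxkit.rate_inference import FitResult
        t = np.linspace(0, 8, 9)
        fits = [FitResult(model="logistic",
                          params={"f0": 0.001, "fmax": 0.9, "k": k},
                          max_loglik=0.0, n_obs=9, n_params=2, aicc=0.0)
                for k in (0.2, 0.4)]
        ens = ensemble_summary(fits, t)
        assert ens.k_mean == pytest.approx(0.3)
        c1 = eval_logistic_fraction(t, 0.001, 0.9, 0.2)
        c2 = eval_logistic_fraction(t, 0.001, 0.9, 0.4)
        assert np.allclose(ens.min_curve, np.minimum(c1, c2))
        assert np.allclose(ens.max_curve, np.maximum(c1, c2))

    def test_envelope_shrinks_with_event_count(self):
        widths = []
        for n_events in (10_000, 1_000_000):
            fits = [fit_exponential(_logistic_counts(
                0.2, 0.9, 0.001, np.linspace(0, 8, 7), n_events, seed=s))
                for s in (11, 12, 13)]
            ens = ensemble_summary(fits, np.linspace(0, 8, 9))
            widths.append((ens.max_curve - ens.min_curve)[-1])
        assert widths[1] < widths[0]


class TestObservedF0:
    def test_zero_count_smoothed(self):
        traj = _count_traj([0.0, 4.0], [0, 50], 10_000)
        assert observed_f0(traj) == pytest.approx(0.5 / 10_001)

    def test_plain_ratio_otherwise(self):
        traj = _count_traj([0.0, 4.0], [13, 50], 10_000)
        assert observed_f0(traj) == pytest.approx(13 / 10_000)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            LogisticParams(f0=0.5, fmax=0.4, k=0.1)
        with pytest.raises(ValueError):
            ExponentialParams(f0=0.0, k=0.1)
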