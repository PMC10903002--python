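import numpy as np
import pandas as pd
import pytest

from progdelay import (
    TrajectorySpec,
    TreatmentEffectSpec,
    TrialDataset,
    delay_confidence_interval,
    fit_pmrm,
    generate_trial,
    pmrm_loglik,
    reference_curve,
)
from progdelay.pmrm import _SplineOps
from progdelay.study import replicate_seed


class TestReferenceCurve:
    def test_constant_everywhere_for_flat_means(self):
        g = reference_curve([2.0] * 6, [0, 6, 12, 18, 24, 36])
        for t in (-3.0, 0.0, 7.5, 36.0, 50.0):
            assert g(t) == pytest.approx(2.0)

    def test_collinear_points_give_the_line(self):
        months = np.array([0.0, 6.0, 12.0, 18.0, 24.0, 36.0])
        g = reference_curve(1.5 + 0.05 * months, months)
        for t in (-6.0, 3.3, 17.7, 30.0, 45.0):
            assert g(t) == pytest.approx(1.5 + 0.05 * t, abs=1e-10)

    def test_interpolates_knots(self, traj):
        g = reference_curve(traj.placebo_means, traj.visit_months)
        for t, y in zip(traj.visit_months, traj.placebo_means):
            assert g(t) == pytest.approx(y, abs=1e-10)

    def test_two_points_fall_back_to_linear_with_warning(self):
        with pytest.warns(UserWarning, match="linear"):
            g = reference_curve([1.0, 2.0], [0.0, 12.0])
        assert g(6.0) == pytest.approx(1.5)

    def test_spline_operator_matches_scipy_curve(self, traj):
        alphas = np.asarray(traj.placebo_means)
        months = np.asarray(traj.visit_months)
        g = reference_curve(alphas, months)
        ops = _SplineOps(months)
        u = np.array([-4.0, 0.0, 2.5, 14.4, 28.8, 36.0, 41.0])
        val_w, der_w = ops.weights(u)
        np.testing.assert_allclose(val_w @ alphas, [g(x) for x in u], atol=1e-12)
        eps = 1e-6
        num = [(g(x + eps) - g(x - eps)) / (2 * eps) for x in u]
        np.testing.assert_allclose(der_w @ alphas, num, atol=1e-6)


class TestFitRecovery:
    def test_noise_free_proportional_delay_recovered(self, traj, effect20):
        zero_traj = TrajectorySpec(
            traj.visit_months, traj.placebo_means, np.zeros((6, 6))
        )
        data = generate_trial(zero_traj, effect20, 10, 36, seed=0)
        fit = fit_pmrm(data)
        assert fit.converged
        # the only error source is the spline-vs-linear interpolation
        # mismatch, a fraction of a month at every visit; on the percent
        # scale it is below one point except at the earliest visit, where
        # dividing by t = 6 months inflates it
        truth = 0.20 * np.asarray(fit.visit_months[1:])
        np.testing.assert_allclose(fit.delays, truth, atol=0.2)
        np.testing.assert_allclose(fit.percent_slowing[1:], 0.20, atol=0.01)

    def test_null_effect_delays_near_zero(self, traj):
        null = TreatmentEffectSpec(0.0)
        n_within = 0
        n_reps = 40
        for rep in range(n_reps):
            data = generate_trial(
                traj, null, 300, 24, seed=replicate_seed(17, 300, 24.0, rep)
            )
            fit = fit_pmrm(data)
            assert fit.converged
            if abs(fit.delays[-1]) <= 2.0 * fit.delay_se[-1]:
                n_within += 1
        assert n_within >= int(0.85 * n_reps)

    def test_optimum_dominates_generative_parameters(self, traj, effect20, noisy_trial):
        fit = fit_pmrm(noisy_trial)
        truth_delays = 0.20 * np.asarray(traj.visit_months[1:])
        ll_truth = pmrm_loglik(
            noisy_trial, traj.placebo_means, truth_delays, traj.covariance
        )
        assert fit.loglik >= ll_truth

    def test_shift_equivariance(self, noisy_trial):
        fit = fit_pmrm(noisy_trial)
        shifted = TrialDataset(
            data=noisy_trial.data.assign(cdr_sb=noisy_trial.data["cdr_sb"] + 5.0),
            n_per_arm=noisy_trial.n_per_arm,
            duration_months=noisy_trial.duration_months,
        )
        fit2 = fit_pmrm(shifted)
        np.testing.assert_allclose(fit2.ref_means, fit.ref_means + 5.0, atol=1e-4)
        np.testing.assert_allclose(fit2.delays, fit.delays, atol=1e-4)

    def test_time_scale_equivariance(self, noisy_trial):
        fit = fit_pmrm(noisy_trial)
        scaled = TrialDataset(
            data=noisy_trial.data.assign(
                visit_month=noisy_trial.data["visit_month"] * 2.0
            ),
            n_per_arm=noisy_trial.n_per_arm,
            duration_months=noisy_trial.duration_months * 2.0,
        )
        fit2 = fit_pmrm(scaled)
        np.testing.assert_allclose(fit2.delays, 2.0 * fit.delays, rtol=1e-3, atol=1e-3)
        np.testing.assert_allclose(
            fit2.percent_slowing, fit.percent_slowing, rtol=1e-3, atol=1e-3
        )

    def test_refit_bit_identical(self, noisy_trial):
        a = fit_pmrm(noisy_trial)
        b = fit_pmrm(noisy_trial)
        np.testing.assert_array_equal(a.delays, b.delays)
        np.testing.assert_array_equal(a.ref_means, b.ref_means)
        np.testing.assert_array_equal(a.fitted_cov, b.fitted_cov)


class TestConfidenceInterval:
    def test_wald_arithmetic(self, noisy_trial):
        fit = fit_pmrm(noisy_trial)
        fit.delays[-1] = 7.2
        fit.delay_se[-1] = 1.0
        lo, hi = delay_confidence_interval(fit, 36.0, level=0.95)
        assert (lo, hi) == (pytest.approx(5.2400, abs=1e-3), pytest.approx(9.1600, abs=1e-3))

    def test_percent_scale_is_month_scale_divided_by_visit(self, noisy_trial):
        fit = fit_pmrm(noisy_trial)
        months = delay_confidence_interval(fit, 36.0)
        pct = delay_confidence_interval(fit, 36.0, scale="percent")
        np.testing.assert_allclose(pct, np.asarray(months) / 36.0)

    def test_zero_se_collapses_to_point(self, noisy_trial):
        fit = fit_pmrm(noisy_trial)
        fit.delay_se = np.zeros_like(fit.delays)
        lo, hi = delay_confidence_interval(fit, 36.0)
        assert lo == hi == pytest.approx(fit.delays[-1])

    def test_missing_se_rejected(self, linear_traj):
        data = generate_trial(linear_traj, TreatmentEffectSpec(0.2), 10, 36, seed=2)
        fit = fit_pmrm(data)  # noise-free: no standard errors
        assert fit.delay_se is None
        with pytest.raises(ValueError, match="unavailable"):
            delay_confidence_interval(fit, 36.0)
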