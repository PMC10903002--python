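import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from progdelay import (
    TrajectorySpec,
    TreatmentEffectSpec,
    TrialDataset,
    dichotomize_progression,
    fit_cox,
    fit_mmrm,
    fit_pmrm,
    generate_trial,
)
from progdelay.comparators import ProgressionEvents


def _make_dataset(records):
    df = pd.DataFrame(records, columns=["subject_id", "arm", "visit_month", "cdr_sb"])
    n = df.groupby("arm")["subject_id"].nunique().max()
    return TrialDataset(data=df, n_per_arm=int(n), duration_months=df["visit_month"].max())


class TestMMRM:
    def test_zero_noise_linear_trajectory_gives_twenty_percent(self, linear_traj):
        data = generate_trial(linear_traj, TreatmentEffectSpec(0.2), 10, 36, seed=0)
        fit = fit_mmrm(data)
        assert fit.percent_reduction == pytest.approx(0.20, abs=1e-10)

    def test_zero_noise_convex_trajectory_hand_value(self, convex_toy_traj):
        # placebo CFB 2.2, active CFB 1.48 -> (2.2 - 1.48) / 2.2
        data = generate_trial(convex_toy_traj, TreatmentEffectSpec(0.2), 8, 36, seed=0)
        fit = fit_mmrm(data)
        assert fit.cfb_diff_final == pytest.approx(0.72, abs=1e-10)
        assert fit.percent_reduction == pytest.approx(0.72 / 2.2, abs=1e-10)

    def test_identical_arms_null_contrast(self, traj):
        data = generate_trial(traj, TreatmentEffectSpec(0.0), 800, 24, seed=31)
        fit = fit_mmrm(data)
        assert abs(fit.cfb_diff_final) < 3.0 * fit.se

    def test_shares_placebo_means_with_pmrm(self, noisy_trial):
        mmrm = fit_mmrm(noisy_trial)
        pmrm = fit_pmrm(noisy_trial)
        np.testing.assert_allclose(
            pmrm.ref_means, mmrm.means_by_arm_visit["placebo"].to_numpy(), atol=1e-6
        )

    def test_cfb_variant_agrees_with_clda_in_zero_noise_linear(self, linear_traj):
        data = generate_trial(linear_traj, TreatmentEffectSpec(0.2), 10, 36, seed=0)
        fit = fit_mmrm(data, model="cfb")
        assert fit.percent_reduction == pytest.approx(0.20, abs=1e-8)

    def test_cfb_variant_close_to_clda_on_noisy_data(self, noisy_trial):
        clda = fit_mmrm(noisy_trial)
        cfb = fit_mmrm(noisy_trial, model="cfb")
        assert cfb.converged
        assert cfb.cfb_diff_final == pytest.approx(clda.cfb_diff_final, abs=0.15)


class TestDichotomize:
    def test_first_crossing_rule(self):
        rows = [(1, "placebo", m, y) for m, y in zip((0, 6, 12, 18), (1.5, 2.0, 4.5, 6.0))]
        rows += [(2, "active", m, y) for m, y in zip((0, 6, 12, 18), (1.0, 1.0, 1.0, 1.0))]
        ev = dichotomize_progression(_make_dataset(rows)).data.set_index("subject_id")
        assert ev.loc[1, "event_time"] == 12 and ev.loc[1, "event_flag"] == 1

    def test_never_crossing_censored_at_last_visit(self, traj):
        months = (0, 6, 12, 18, 24, 36)
        rows = [(1, "placebo", m, 2.0) for m in months]
        rows += [(2, "active", m, 1.0) for m in months]
        ev = dichotomize_progression(_make_dataset(rows)).data.set_index("subject_id")
        assert ev.loc[1, "event_time"] == 36 and ev.loc[1, "event_flag"] == 0

    def test_baseline_above_threshold_is_not_an_event(self):
        rows = [(1, "placebo", m, y) for m, y in zip((0, 6, 12), (4.6, 4.7, 4.8))]
        rows += [(2, "active", m, y) for m, y in zip((0, 6, 12), (1.0, 1.0, 1.0))]
        ev = dichotomize_progression(_make_dataset(rows)).data.set_index("subject_id")
        assert ev.loc[1, "event_time"] == 6 and ev.loc[1, "event_flag"] == 1

    @given(th1=st.floats(2.0, 8.0), th2=st.floats(2.0, 8.0))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_raising_threshold_never_advances_events(self, traj, th1, th2, effect20):
        lo, hi = sorted((th1, th2))
        data = generate_trial(traj, effect20, 40, 36, seed=13)
        ev_lo = dichotomize_progression(data, threshold=lo).data
        ev_hi = dichotomize_progression(data, threshold=hi).data
        assert (ev_hi["event_time"] >= ev_lo["event_time"]).all()
        assert (ev_hi["event_flag"] <= ev_lo["event_flag"]).all()


def _efron_negloglik(beta, times, flags, x):
    """Independent brute-force Efron partial likelihood."""
    ll = 0.0
    for t in np.unique(times[flags]):
        dead = flags & (times == t)
        risk = times >= t
        d = int(dead.sum())
        sum_dead_x = x[dead].sum()
        r_total = np.exp(beta * x[risk]).sum()
        d_total = np.exp(beta * x[dead]).sum()
        ll += beta * sum_dead_x
        for ell in range(d):
            ll -= np.log(r_total - (ell / d) * d_total)
    return -ll


class TestCox:
    TOY_EVENTS = pd.DataFrame(
        {
            "subject_id": [1, 2, 3, 4, 5, 6],
            "arm": ["placebo"] * 3 + ["active"] * 3,
            "event_time": [6.0, 12.0, 18.0, 12.0, 18.0, 36.0],
            "event_flag": [1, 1, 1, 1, 1, 1],
        }
    )

    def test_identical_event_data_gives_unit_hazard_ratio(self):
        df = pd.concat(
            [
                self.TOY_EVENTS.assign(arm="placebo"),
                self.TOY_EVENTS.assign(arm="active", subject_id=lambda d: d.subject_id + 6),
            ],
            ignore_index=True,
        )
        fit = fit_cox(ProgressionEvents(data=df, threshold=4.5))
        assert fit.hazard_ratio == pytest.approx(1.0, abs=1e-6)

    def test_toy_set_matches_brute_force_partial_likelihood(self):
        fit = fit_cox(ProgressionEvents(data=self.TOY_EVENTS, threshold=4.5))
        times = self.TOY_EVENTS["event_time"].to_numpy()
        flags = self.TOY_EVENTS["event_flag"].to_numpy().astype(bool)
        x = (self.TOY_EVENTS["arm"] == "active").to_numpy().astype(float)
        res = minimize_scalar(
            _efron_negloglik, args=(times, flags, x), bounds=(-5, 5), method="bounded"
        )
        assert np.log(fit.hazard_ratio) == pytest.approx(res.x, abs=1e-4)

    def test_time_rescaling_leaves_hazard_ratio_unchanged(self):
        fit_m = fit_cox(ProgressionEvents(data=self.TOY_EVENTS, threshold=4.5))
        years = self.TOY_EVENTS.assign(event_time=self.TOY_EVENTS["event_time"] / 12.0)
        fit_y = fit_cox(ProgressionEvents(data=years, threshold=4.5))
        assert fit_m.hazard_ratio == pytest.approx(fit_y.hazard_ratio, rel=1e-8)

    def test_zero_events_flagged_non_estimable(self):
        df = self.TOY_EVENTS.assign(event_flag=0)
        fit = fit_cox(ProgressionEvents(data=df, threshold=4.5))
        assert not fit.estimable and fit.hazard_ratio is None

    def test_breslow_option_close_to_efron_on_toy_set(self):
        ev = ProgressionEvents(data=self.TOY_EVENTS, threshold=4.5)
        efron = fit_cox(ev)
        breslow = fit_cox(ev, ties="breslow")
        assert breslow.estimable
        assert np.sign(np.log(breslow.hazard_ratio)) == np.sign(np.log(efron.hazard_ratio))

    def test_slowed_arm_has_protective_hazard_ratio(self, traj, effect20):
        hrs = []
        for seed in range(5):
            data = generate_trial(traj, effect20, 400, 36, seed=100 + seed)
            fit = fit_cox(dichotomize_progression(data))
            assert fit.estimable
            hrs.append(fit.hazard_ratio)
        assert np.median(hrs) < 1.0
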