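"""Synthetic jump generator: stance profile, ballistics, legs, noise, truth."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from saltijump.errors import FeasibilityError, ScheduleError
from saltijump.kinematics import GRAVITY
from saltijump.choreography import JOINT_NAMES, LegChain, effective_leg_length
from saltijump.synthetic import (
    LegSchedule,
    SimParams,
    add_tracking_noise,
    paper_like_params,
    simulate_com,
    simulate_legs,
    simulate_study,
    simulate_trial,
    solve_accel_profile,
)


class TestAccelProfile:
    def test_symmetric_case_has_unit_exponent(self):
        """A=100, T=20 ms, f=0.5, v=1.0 solves to p=1 (quadrature-checked)."""
        prof = solve_accel_profile(100.0, 1.0, 20.0, 0.5)
        assert prof.p == pytest.approx(1.0, abs=1e-12)
        integral, _ = quad(prof.a, 0, prof.T, limit=200)
        assert integral == pytest.approx(1.0, abs=1e-9)

    def test_male_means_integrate_to_takeoff_velocity(self):
        prof = solve_accel_profile(127.8, 0.84, 20.8, 0.85)
        integral, _ = quad(prof.a, 0, prof.T, limit=200)
        assert integral == pytest.approx(0.84, abs=1e-6)
        # maximum attained exactly at t_p
        t = np.linspace(0, prof.T, 20001)
        assert prof.a(prof.tp) == pytest.approx(127.8, rel=1e-12)
        assert np.max(prof.a(t)) <= 127.8 + 1e-9

    def test_velocity_at_upper_bound_is_infeasible(self):
        with pytest.raises(FeasibilityError, match="achievable interval"):
            solve_accel_profile(100.0, 100.0 * 0.020, 20.0, 0.5)

    def test_error_reports_achievable_interval(self):
        with pytest.raises(FeasibilityError, match=r"\("):
            solve_accel_profile(100.0, 0.01, 20.0, 0.5)  # below lower bound

    def test_closed_form_velocity_matches_quadrature(self):
        prof = solve_accel_profile(127.8, 0.84, 20.8, 0.85)
        for t in (0.003, 0.011, 0.0177, 0.0201):
            # split the quadrature at the profile's interior kink
            pts = [prof.tp] if t > prof.tp else None
            num, _ = quad(prof.a, 0, t, limit=200, points=pts)
            assert prof.v(t) == pytest.approx(num, abs=1e-9)


class TestSimulateCom:
    def test_flight_vertical_acceleration_is_minus_g(self, male_sim):
        trial, truth = male_sim
        com = trial.com
        dt = trial.meta.frame_interval
        i0 = truth.all_legs_off_frame + 2
        t = np.arange(i0, com.n_frames) * dt * 1e-3  # s
        y = com.y[i0:] * 1e-3  # m
        coef = np.polyfit(t, y, 2)
        assert 2 * coef[0] == pytest.approx(-GRAVITY, rel=0.005)

    def test_flight_peak_height_matches_closed_form_ballistics(self, male_sim):
        trial, truth = male_sim
        v, ang = truth.v_max, math.radians(truth.takeoff_angle)
        rise = (v * math.sin(ang)) ** 2 / (2 * GRAVITY) * 1000.0  # mm
        assert rise == pytest.approx(6.46, abs=0.01)  # sanity on the closed form
        y_to = truth.flight_start_xy[1]
        assert np.max(trial.com.y) - y_to == pytest.approx(rise, abs=0.01)

    def test_trajectory_spans_the_gap(self, male_sim):
        trial, _ = male_sim
        assert np.nanmax(trial.com.x) - trial.com.x[0] >= trial.meta.gap

    def test_flight_energy_bookkeeping(self, male_sim):
        """v_y^2 + 2 g (y - y_to) is conserved along noise-free flight."""
        trial, truth = male_sim
        com = trial.com
        dt = trial.meta.frame_interval
        g = GRAVITY * 1e-3  # mm/ms^2
        i0, i1 = truth.all_legs_off_frame + 2, com.n_frames - 2
        vy = (com.y[i0 + 1 : i1 + 1] - com.y[i0 - 1 : i1 - 1]) / (2 * dt)
        e = vy**2 + 2 * g * (com.y[i0:i1] - truth.flight_start_xy[1])
        assert np.ptp(e) / np.mean(np.abs(e)) < 1e-3

    def test_event_order_matches_observed_choreography(self, male_sim, female_sim):
        for trial, truth in (male_sim, female_sim):
            lo = truth.liftoff_frames
            assert lo["L1"] == lo["L2"] == 0  # raised throughout
            assert truth.onset_frame <= truth.abdomen_touch_frame
            assert truth.abdomen_touch_frame <= lo["L4"]
            assert lo["L4"] <= lo["L3"] == truth.all_legs_off_frame
            # leg IV leaves near peak acceleration, leg III after it
            assert abs(lo["L4"] - truth.peak_accel_frame) <= 2
            assert lo["L3"] > truth.peak_accel_frame


class TestSimulateLegs:
    def test_ell_is_one_at_scheduled_full_extension(self, male_sim):
        trial, truth = male_sim
        for leg in ("L3", "L4"):
            chain = LegChain.from_trial(trial, leg)
            ell = effective_leg_length(chain)
            assert ell[truth.max_ell_frames[leg]] == pytest.approx(1.0, abs=1e-9)

    def test_claw_pinned_until_liftoff_then_rises(self, male_sim):
        trial, truth = male_sim
        platform = trial.meta.platform_y
        for leg in ("L3", "L4"):
            claw = trial.tracks[f"{leg}_tarsal_claw"]
            lo = truth.liftoff_frames[leg]
            np.testing.assert_array_equal(claw.y[:lo], platform)
            assert claw.y[lo] > platform

    def test_segment_lengths_constant_over_all_frames(self, male_sim):
        trial, _ = male_sim
        for leg in ("L1", "L2", "L3", "L4"):
            joints = [trial.tracks[f"{leg}_{j}"] for j in JOINT_NAMES]
            for k in range(3):
                d = np.hypot(
                    joints[k + 1].x - joints[k].x, joints[k + 1].y - joints[k].y
                )
                assert np.ptp(d) / d[0] < 1e-9

    def test_extension_after_liftoff_is_a_schedule_error(self):
        sched = {
            "L1": LegSchedule(raised=True),
            "L2": LegSchedule(raised=True),
            "L3": LegSchedule(initial_ell=0.3, full_extension_ms=20.0, liftoff_ms=10.0),
            "L4": LegSchedule(initial_ell=0.3, full_extension_ms=9.0, liftoff_ms=11.0),
        }
        with pytest.raises(ScheduleError, match="L3"):
            SimParams(leg_schedule=sched)

    def test_duplicate_liftoff_times_rejected(self):
        sched = {
            "L3": LegSchedule(initial_ell=0.3, full_extension_ms=17.0, liftoff_ms=17.0),
            "L4": LegSchedule(initial_ell=0.3, full_extension_ms=17.0, liftoff_ms=17.0),
        }
        with pytest.raises(ScheduleError, match="distinct"):
            SimParams(leg_schedule=sched)


class TestTrackingNoise:
    def test_zero_noise_is_identity(self, male_sim):
        trial, _ = male_sim
        noisy = add_tracking_noise(trial, 0.0, seed=5)
        np.testing.assert_array_equal(noisy.com.x, trial.com.x)

    def test_same_seed_reproduces(self, male_sim):
        trial, _ = male_sim
        a = add_tracking_noise(trial, 0.02, seed=7)
        b = add_tracking_noise(trial, 0.02, seed=7)
        np.testing.assert_array_equal(a.com.x, b.com.x)
        c = add_tracking_noise(trial, 0.02, seed=8)
        assert not np.array_equal(a.com.x, c.com.x)

    def test_original_unmodified(self, male_sim):
        trial, _ = male_sim
        before = trial.com.x.copy()
        add_tracking_noise(trial, 0.05, seed=1)
        np.testing.assert_array_equal(trial.com.x, before)

    def test_empirical_noise_sd(self, male_sim):
        trial, _ = male_sim
        sd = 0.03
        deltas = []
        seed = 11
        while sum(len(d) for d in deltas) < 10**5:
            noisy = add_tracking_noise(trial, sd, seed=seed)
            for name in trial.tracks:
                deltas.append(noisy.tracks[name].x - trial.tracks[name].x)
                deltas.append(noisy.tracks[name].y - trial.tracks[name].y)
            seed += 1
        emp = np.std(np.concatenate(deltas))
        assert emp == pytest.approx(sd, rel=0.02)


class TestParameterRecovery:
    """Full-pipeline recovery of the generator parameters (noise-free).

    The acceleration peak carries a small one-frame-interval averaging
    bias (the profile maximum is a corner), so its recovery tolerance is
    2% rather than 1%; velocity, angle and duration recover within 1%
    / two frame intervals.
    """

    @pytest.mark.parametrize("sex", ["male", "female"])
    def test_recovery_at_sex_means(self, sex, male_analysis, female_analysis):
        from saltijump.synthetic import SEX_MEANS

        events, result, chron, call = male_analysis if sex == "male" else female_analysis
        m = SEX_MEANS[sex]
        assert result.takeoff_velocity_m_per_s == pytest.approx(
            m["takeoff_velocity"], rel=0.01
        )
        assert result.takeoff_angle_deg == pytest.approx(m["takeoff_angle"], rel=0.01)
        assert result.takeoff_duration_ms == pytest.approx(
            m["takeoff_duration"], abs=2 * 0.2
        )
        assert result.peak_acceleration_m_per_s2 == pytest.approx(
            m["peak_accel"], rel=0.02
        )

    def test_increasing_peak_accel_increases_estimate(self):
        from saltijump.pipeline import RunConfig, analyze_trial

        est = []
        for a in (105.0, 120.0, 135.0):
            trial, _ = simulate_trial(paper_like_params("male", peak_accel=a))
            _, result, _, _ = analyze_trial(trial, RunConfig())
            est.append(result.peak_acceleration_m_per_s2)
        assert est[0] < est[1] < est[2]


def test_simulate_study_counts_and_determinism():
    trials = simulate_study(n_male_subjects=2, n_female_subjects=2, seed=3)
    # 2 males x 3 + 1 female x 3 + 1 female x 2 (study-count emulation)
    assert len(trials) == 11
    sexes = [t.meta.sex for t, _ in trials]
    assert sexes.count("male") == 6 and sexes.count("female") == 5
    again = simulate_study(n_male_subjects=2, n_female_subjects=2, seed=3)
    np.testing.assert_array_equal(trials[0][0].com.x, again[0][0].com.x)
    # masses constant within subject
    by_subject = {}
    for t, _ in trials:
        by_subject.setdefault(t.meta.subject_id, set()).add(t.meta.body_mass)
    assert all(len(v) == 1 for v in by_subject.values())
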