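"""Event detection and the kinematic panel: oracles and invariances."""

import dataclasses
import math

import numpy as np
import pytest

from saltijump.errors import (
    DegenerateAngleError,
    IncompleteTrajectoryError,
    NoMovementError,
)
from saltijump.io_tracks import PointTrack, TrackedTrial, TrialMeta
from saltijump.kinematics import (
    JumpEvents,
    acceleration_series,
    derived_quantities,
    detect_onset,
    takeoff_angle,
    takeoff_metrics,
    trajectory_heights,
    velocity_series,
)


def track(x, y, name="CoM"):
    return PointTrack(name, np.asarray(x, float), np.asarray(y, float))


class TestVelocitySeries:
    def test_uniform_motion_gives_constant_speed(self):
        t = track([0, 0.168, 0.336], [0, 0, 0])
        np.testing.assert_allclose(velocity_series(t, 0.2), [0.84, 0.84])

    def test_constant_position_gives_zeros(self):
        t = track([3, 3, 3, 3], [1, 1, 1, 1])
        np.testing.assert_allclose(velocity_series(t, 0.2), 0.0)

    def test_speed_is_isotropic(self):
        tx = track([0, 0.1, 0.25, 0.45], [0, 0, 0, 0])
        ty = track([0, 0, 0, 0], [0, 0.1, 0.25, 0.45])
        np.testing.assert_allclose(velocity_series(tx, 0.2), velocity_series(ty, 0.2))

    def test_speed_is_rotation_invariant(self):
        rng = np.random.default_rng(0)
        x, y = np.cumsum(rng.normal(size=20)), np.cumsum(rng.normal(size=20))
        base = velocity_series(track(x, y), 0.2)
        for ang in (0.3, 1.1, 2.9):
            c, s = math.cos(ang), math.sin(ang)
            rot = velocity_series(track(c * x - s * y, s * x + c * y), 0.2)
            np.testing.assert_allclose(rot, base, rtol=1e-9)


class TestAccelerationSeries:
    def test_constant_speed_increment(self):
        a = acceleration_series([0, 0.02556, 0.05112], 0.2)
        np.testing.assert_allclose(a, [127.8, 127.8])

    def test_constant_speed_gives_zeros(self):
        np.testing.assert_allclose(acceleration_series([0.5] * 5, 0.2), 0.0)

    def test_quadratic_position_recovers_acceleration(self):
        a_true = 80.0  # m/s^2
        dt = 0.2  # ms
        t = np.arange(200) * dt * 1e-3  # s
        x_mm = 0.5 * a_true * t**2 * 1000.0
        speed = velocity_series(track(x_mm, np.zeros_like(x_mm)), dt)
        accel = acceleration_series(speed, dt)
        np.testing.assert_allclose(accel, a_true, rtol=1e-6)


class TestDetectOnset:
    def test_noise_free_step_detected_exactly(self):
        x = np.concatenate([np.zeros(50), np.arange(1, 31) * 0.05])
        onset, sigma = detect_onset(track(x, np.zeros_like(x)), baseline_frames=30)
        assert onset == 50
        assert sigma == 0.0

    def test_noisy_step_onset_within_two_frames(self):
        """Step-velocity motion: >= 95% of replicates within 2 frames."""
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 200
        true_onset = 120
        v = 0.4  # mm/ms: displacement per frame 0.08 mm vs noise 0.01 mm
        for _ in range(n_rep):
            x = np.concatenate(
                [np.zeros(true_onset), np.arange(1, 120) * v * 0.2]
            ) + rng.normal(0, 0.01, true_onset + 119)
            y = rng.normal(0, 0.01, len(x))
            try:
                onset, _ = detect_onset(track(x, y), 50, 3.0, 5)
            except NoMovementError:
                continue
            hits += abs(onset - true_onset) <= 2
        assert hits / n_rep >= 0.95

    def test_stationary_noisy_track_raises(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.01, 300)
        y = rng.normal(0, 0.01, 300)
        with pytest.raises(NoMovementError):
            detect_onset(track(x, y), 50, 3.0, 5)

    def test_detection_never_early_on_smooth_simulation(self, male_analysis, male_sim):
        _, truth = male_sim
        events, _, _, _ = male_analysis
        assert events.onset_frame >= truth.onset_frame
        assert events.onset_frame - truth.onset_frame <= 2  # noise-free: immediate


class TestDerivedQuantities:
    def test_identity_constraints_hold_exactly(self):
        panel = derived_quantities(7.3, 0.91, 118.0, 19.5)
        assert panel["g_force"] * 9.81 == pytest.approx(118.0, rel=1e-12)
        assert panel["kinetic_energy_uJ"] == pytest.approx(
            0.5 * 7.3 * 0.91**2, rel=1e-12
        )
        assert panel["jump_power_mW"] == pytest.approx(
            panel["kinetic_energy_uJ"] / 19.5, rel=1e-12
        )
        assert panel["jump_force_mN"] == pytest.approx(7.3 * 118.0 * 1e-3, rel=1e-12)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            derived_quantities(0.0, 0.8, 100.0, 20.0)


class TestTakeoffAngle:
    def test_example_displacement(self):
        t = track([0, 3.62], [0, 1.69])
        assert takeoff_angle(t, 0, 1) == pytest.approx(25.03, abs=0.01)

    def test_horizontal_displacement_is_zero_deg(self):
        t = track([0, 1], [0, 0])
        assert takeoff_angle(t, 0, 1) == 0.0

    def test_zero_displacement_is_degenerate(self):
        t = track([1, 1, 2], [2, 2, 2])
        with pytest.raises(DegenerateAngleError):
            takeoff_angle(t, 0, 1)

    def test_simulated_jump_angle_recovered(self, male_analysis, male_sim):
        _, truth = male_sim
        _, result, _, _ = male_analysis
        assert result.takeoff_angle_deg == pytest.approx(truth.takeoff_angle, abs=0.1)


class TestTrajectoryHeights:
    def test_simulated_flight_peak_matches_ballistics(self, male_sim):
        trial, truth = male_sim
        v, ang = truth.v_max, math.radians(truth.takeoff_angle)
        rise = (v * math.sin(ang)) ** 2 / (2 * 9.81) * 1000.0
        peak, end = trajectory_heights(
            trial.com, trial.meta.platform_y, trial.meta.gap
        )
        expected = truth.flight_start_xy[1] - trial.meta.platform_y + rise
        assert peak == pytest.approx(expected, abs=0.01)
        assert end < peak

    def test_descending_trajectory_peaks_at_first_frame(self):
        x = np.linspace(0, 50, 40)
        y = 10 - 0.3 * x
        peak, end = trajectory_heights(track(x, y), 0.0, 40.0)
        assert peak == pytest.approx(10.0)
        assert end == pytest.approx(10 - 0.3 * 40)

    def test_gap_beyond_trajectory_raises(self):
        t = track([0, 5, 10], [0, 1, 2])
        with pytest.raises(IncompleteTrajectoryError):
            trajectory_heights(t, 0.0, 40.0)

    def test_end_height_linearly_interpolated(self):
        t = track([0, 30, 50], [0, 3, 7])
        _, end = trajectory_heights(t, 0.0, 40.0)
        assert end == pytest.approx(5.0)


class TestPanelInvariances:
    def test_translation_leaves_magnitudes_unchanged(self, male_sim, male_analysis):
        trial, _ = male_sim
        events, base, _, _ = male_analysis
        shifted = TrackedTrial(
            meta=trial.meta,
            tracks={
                "CoM": PointTrack("CoM", trial.com.x + 13.5, trial.com.y - 2.25)
            },
        )
        res = takeoff_metrics(shifted, events)
        for name in (
            "takeoff_velocity_m_per_s",
            "peak_acceleration_m_per_s2",
            "kinetic_energy_uJ",
            "g_force",
            "takeoff_angle_deg",
            "takeoff_duration_ms",
        ):
            assert getattr(res, name) == pytest.approx(getattr(base, name), rel=1e-9)

    def test_x_reflection_flips_angle_only(self, male_sim, male_analysis):
        trial, _ = male_sim
        events, base, _, _ = male_analysis
        reflected = TrackedTrial(
            meta=trial.meta,
            tracks={"CoM": PointTrack("CoM", -trial.com.x, trial.com.y)},
        )
        res = takeoff_metrics(reflected, events)
        assert res.takeoff_angle_deg == pytest.approx(
            180 - base.takeoff_angle_deg, rel=1e-9
        )
        assert res.takeoff_velocity_m_per_s == pytest.approx(
            base.takeoff_velocity_m_per_s, rel=1e-9
        )
        assert res.peak_acceleration_m_per_s2 == pytest.approx(
            base.peak_acceleration_m_per_s2, rel=1e-9
        )

    def test_2x_downsampling_changes_vmax_apeak_under_2pct(
        self, male_sim, male_analysis
    ):
        trial, truth = male_sim
        _, base, _, _ = male_analysis
        com = trial.com
        half = PointTrack("CoM", com.x[::2], com.y[::2])
        dt2 = trial.meta.frame_interval * 2
        speed = velocity_series(half, dt2)
        accel = acceleration_series(speed, dt2)
        on, off = truth.onset_frame // 2, truth.all_legs_off_frame // 2
        v2 = np.nanmax(speed[max(on - 1, 0) : off])
        a2 = np.nanmax(accel[max(on - 1, 0) : off - 1])
        assert v2 == pytest.approx(base.takeoff_velocity_m_per_s, rel=0.02)
        assert a2 == pytest.approx(base.peak_acceleration_m_per_s2, rel=0.02)

    def test_events_out_of_range_rejected(self, male_sim):
        trial, _ = male_sim
        events = JumpEvents(
            onset_frame=10,
            abdomen_move_frame=9,
            all_legs_off_frame=trial.frame_count + 5,
            peak_accel_frame=50,
        )
        from saltijump.errors import EventError

        with pytest.raises(EventError):
            takeoff_metrics(trial, events)
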