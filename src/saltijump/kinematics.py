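"""Jump-event detection and the per-jump kinematic panel.

Take-off is the window from the first detectable CoM movement to the first
frame with all legs off the substrate.  Within that window the pipeline
computes, per frame, speed v = d/t and acceleration a = dv/dt, and derives
the panel reported for each jump:

    kinetic energy  ke = 1/2 m v_max^2        (uJ)
    jump force      F  = m a_peak             (mN)
    jump power      P  = ke / take-off time   (mW)
    g-force         g  = a_peak / 9.81        (dimensionless)

plus the take-off angle of the CoM displacement (relative to the substrate
plane) between the frame before the abdomen moves and the all-legs-off
frame, and — for full trajectories — the trajectory peak height and the
height when the animal reaches the landing platform.

Coordinates are mm, time is ms, so mm/ms is numerically m/s.  Speed is the
scalar norm of the 2-D displacement (path speed).  Differentiation is raw
first-difference by default; at 0.2 ms frame intervals double-differencing
amplifies tracking noise, so an optional centered moving-average window is
provided for noisy data (see ``smooth_window``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateAngleError,
    EmptyTrackError,
    EventError,
    IncompleteTrajectoryError,
    NoMovementError,
)
from .io_tracks import PointTrack, TrackedTrial

__all__ = [
    "GRAVITY",
    "JumpEvents",
    "KinematicsResult",
    "velocity_series",
    "acceleration_series",
    "detect_onset",
    "detect_takeoff_end",
    "takeoff_angle",
    "takeoff_metrics",
    "derived_quantities",
    "peak_acceleration_frame",
    "trajectory_heights",
]

#: Standard gravitational acceleration used for the g-force panel (m s^-2).
GRAVITY = 9.81


@dataclass
class JumpEvents:
    """Detected frame indices for the events that delimit one jump."""

    onset_frame: int
    abdomen_move_frame: int
    all_legs_off_frame: int
    peak_accel_frame: int
    per_leg_liftoff: dict[str, int | None] = field(default_factory=dict)
    onset_noise_floor: float = float("nan")

    def validate(self, n_frames: int) -> None:
        if not (0 <= self.onset_frame <= self.all_legs_off_frame < n_frames):
            raise EventError(
                f"events out of range: onset={self.onset_frame}, "
                f"all_legs_off={self.all_legs_off_frame}, n_frames={n_frames}"
            )
        if not (0 <= self.peak_accel_frame < n_frames):
            raise EventError(f"peak_accel_frame {self.peak_accel_frame} out of range")
        if not (0 <= self.abdomen_move_frame < n_frames):
            raise EventError(f"abdomen_move_frame {self.abdomen_move_frame} out of range")


@dataclass
class KinematicsResult:
    """The kinematic panel for one jump.

    Invariant by construction: g_force * 9.81 == a_peak,
    kinetic_energy == 1/2 m v_max^2 and jump_power == ke / duration —
    these are definitions, not estimates.
    """

    takeoff_duration_ms: float
    takeoff_velocity_m_per_s: float
    peak_acceleration_m_per_s2: float
    kinetic_energy_uJ: float
    jump_force_mN: float
    jump_power_mW: float
    g_force: float
    takeoff_angle_deg: float
    peak_height_mm: float = float("nan")
    end_height_mm: float = float("nan")
    trial_id: str = "trial"
    subject_id: str = "subject"
    sex: str = ""
    body_mass_mg: float = float("nan")

    def as_row(self) -> dict:
        return dict(self.__dict__)


def _smoothed(values: np.ndarray, window: int) -> np.ndarray:
    if window < 1 or window % 2 == 0:
        raise ValueError("smooth_window must be odd and >= 1")
    if window == 1:
        return values
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(values, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def velocity_series(
    com: PointTrack, frame_interval: float, smooth_window: int = 1
) -> np.ndarray:
    """Per-frame path speed (m/s) from consecutive CoM displacements.

    Element ``i`` is the speed over the interval between frames ``i`` and
    ``i+1``; the series has length ``n_frames - 1``.  Frames with missing
    CoM yield NaN speeds.
    """
    if not com.finite_mask().any():
        raise EmptyTrackError(f"track {com.name!r} is all-missing")
    x = _smoothed(com.x, smooth_window)
    y = _smoothed(com.y, smooth_window)
    return np.hypot(np.diff(x), np.diff(y)) / frame_interval


def acceleration_series(speed: np.ndarray, frame_interval: float) -> np.ndarray:
    """First difference of speed over time (m s^-2).

    Element ``j`` spans speed samples ``j`` and ``j+1`` and is attributed
    to frame ``j + 1``.  ``frame_interval`` is in ms.
    """
    speed = np.asarray(speed, dtype=float)
    if len(speed) < 2:
        raise ValueError("speed series needs at least 2 samples")
    return np.diff(speed) / (frame_interval * 1e-3)


def detect_onset(
    com: PointTrack,
    baseline_frames: int = 50,
    k: float = 3.0,
    persist: int = 5,
) -> tuple[int, float]:
    """First frame of sustained CoM movement above the tracking-noise floor.

    The noise floor sigma is the s.d. of the frame-to-frame displacement
    magnitude over the first ``baseline_frames`` (which must precede any
    motion).  Onset is the first frame whose displacement from the previous
    frame exceeds ``k * sigma`` for ``persist`` consecutive frames.

    Returns (onset_frame, sigma).  On noise-free data sigma is 0 and any
    nonzero displacement triggers.
    """
    if k <= 0 or persist < 1:
        raise ValueError("k must be > 0 and persist >= 1")
    disp = np.hypot(np.diff(com.x), np.diff(com.y))
    if baseline_frames < 2 or baseline_frames > len(disp):
        raise ValueError("baseline window must contain 2..n_frames-1 displacements")
    sigma = float(np.nanstd(disp[:baseline_frames]))
    threshold = k * sigma
    above = disp > threshold
    above[~np.isfinite(disp)] = False
    # displacement i is between frames i and i+1 -> movement visible at i+1
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= persist:
            return i - persist + 2, sigma
    raise NoMovementError(
        f"no {persist}-frame run of displacement above {threshold:.4g} mm"
    )


def detect_takeoff_end(
    accel: np.ndarray, peak_index: int, persist: int = 3
) -> int:
    """Fallback all-legs-off estimate for trials without leg tracks.

    Once airborne the path acceleration from CoM speeds is non-positive
    (ballistic deceleration), so the end of stance is taken as the first
    frame after the acceleration peak where the acceleration stays <= 0
    for ``persist`` samples.  Returns a frame index (accel sample j maps
    to frame j + 1).
    """
    run = 0
    for j in range(peak_index, len(accel)):
        run = run + 1 if accel[j] <= 0 else 0
        if run >= persist:
            return (j - persist + 1) + 1
    raise EventError("acceleration never settles to <= 0 after its peak")


def derived_quantities(
    body_mass_mg: float,
    v_max: float,
    a_peak: float,
    duration_ms: float,
) -> dict[str, float]:
    """The derived panel from its defining identities, in reported units.

    ke = 1/2 m v^2 (uJ), F = m a (mN), P = ke/duration (mW), g = a/9.81.
    With mass in mg, v in m/s, a in m/s^2 and duration in ms the unit
    conversions collapse to ke_uJ = 0.5 * m_mg * v^2, F_mN = m_mg * a / 1000
    and P_mW = ke_uJ / duration_ms.
    """
    if body_mass_mg <= 0:
        raise ValueError("body mass must be > 0")
    ke = 0.5 * body_mass_mg * v_max**2
    return {
        "kinetic_energy_uJ": ke,
        "jump_force_mN": body_mass_mg * a_peak * 1e-3,
        "jump_power_mW": ke / duration_ms,
        "g_force": a_peak / GRAVITY,
    }


def takeoff_angle(
    com: PointTrack, abdomen_move_frame: int, all_legs_off_frame: int
) -> float:
    """Take-off angle (deg) of the CoM displacement relative to the substrate.

    Measured between the first frame prior to abdomen movement and the
    first frame with all legs off the ground; the substrate plane is the
    x axis.  Result lies in (-90, 90).
    """
    x0, y0 = com.x[abdomen_move_frame], com.y[abdomen_move_frame]
    x1, y1 = com.x[all_legs_off_frame], com.y[all_legs_off_frame]
    if not (np.isfinite(x0) and np.isfinite(y0) and np.isfinite(x1) and np.isfinite(y1)):
        raise EventError("CoM is missing at an angle-defining frame")
    dx, dy = x1 - x0, y1 - y0
    if dx == 0 and dy == 0:
        raise DegenerateAngleError("zero CoM displacement between angle frames")
    return math.degrees(math.atan2(dy, dx))


def takeoff_metrics(
    trial: TrackedTrial,
    events: JumpEvents,
    smooth_window: int = 1,
) -> KinematicsResult:
    """Compute the full kinematic panel for one jump.

    Maxima of speed and acceleration are taken within the take-off window
    [onset, all_legs_off]; the derived quantities follow from their
    defining identities (see :func:`derived_quantities`).
    """
    com = trial.com
    events.validate(trial.frame_count)
    if events.all_legs_off_frame <= events.onset_frame:
        raise EventError("all_legs_off must come after onset")
    dt = trial.meta.frame_interval
    speed = velocity_series(com, dt, smooth_window)
    accel = acceleration_series(speed, dt)

    on, off = events.onset_frame, events.all_legs_off_frame
    # speed sample i spans frames [i, i+1]; keep samples inside the window
    s_win = speed[max(on - 1, 0) : off]
    a_win = accel[max(on - 1, 0) : off - 1]
    if not np.isfinite(s_win).any() or not np.isfinite(a_win).any():
        raise EmptyTrackError("no finite speed/acceleration samples in take-off window")
    v_max = float(np.nanmax(s_win))
    a_peak = float(np.nanmax(a_win))
    duration = (off - on) * dt
    panel = derived_quantities(trial.meta.body_mass, v_max, a_peak, duration)

    angle = takeoff_angle(com, events.abdomen_move_frame, events.all_legs_off_frame)
    try:
        peak_h, end_h = trajectory_heights(com, trial.meta.platform_y, trial.meta.gap)
    except IncompleteTrajectoryError:
        peak_h = end_h = float("nan")

    return KinematicsResult(
        takeoff_duration_ms=duration,
        takeoff_velocity_m_per_s=v_max,
        peak_acceleration_m_per_s2=a_peak,
        takeoff_angle_deg=angle,
        peak_height_mm=peak_h,
        end_height_mm=end_h,
        trial_id=trial.meta.trial_id,
        subject_id=trial.meta.subject_id,
        sex=trial.meta.sex,
        body_mass_mg=trial.meta.body_mass,
        **panel,
    )


def peak_acceleration_frame(accel: np.ndarray, onset_frame: int = 0) -> int:
    """Frame of the acceleration maximum (first occurrence on ties).

    Acceleration sample j is attributed to frame j + 1; the search starts
    at the onset frame.
    """
    j0 = max(onset_frame - 1, 0)
    seg = np.asarray(accel[j0:], dtype=float)
    if not np.isfinite(seg).any():
        raise EmptyTrackError("no finite acceleration samples after onset")
    return int(np.nanargmax(seg)) + j0 + 1


def trajectory_heights(
    com: PointTrack, platform_y: float, gap: float
) -> tuple[float, float]:
    """Trajectory peak height and height on reaching the landing platform.

    Heights are above the take-off surface (mm).  The end height is the
    CoM y, linearly interpolated, at the first horizontal crossing of the
    gap distance measured from the trajectory start.
    """
    mask = com.finite_mask()
    x = com.x[mask]
    y = com.y[mask]
    if len(x) < 2:
        raise EmptyTrackError("trajectory has fewer than 2 finite frames")
    x_rel = x - x[0]
    crossing = np.nonzero(x_rel >= gap)[0]
    if len(crossing) == 0:
        raise IncompleteTrajectoryError(
            f"trajectory spans {np.nanmax(x_rel):.2f} mm < gap {gap:.2f} mm"
        )
    i = int(crossing[0])
    if i == 0 or x_rel[i] == gap:
        y_end = y[i]
    else:
        f = (gap - x_rel[i - 1]) / (x_rel[i] - x_rel[i - 1])
        y_end = y[i - 1] + f * (y[i] - y[i - 1])
    peak = float(np.max(y[: i + 1]) - platform_y)
    return peak, float(y_end - platform_y)
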