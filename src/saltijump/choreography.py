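"""Per-leg extension choreography and propulsive-leg classification.

Salticid legs lack extensor muscles; extension is hydraulic, and which leg
keeps pushing after the others have left the substrate identifies the
propulsive leg.  Two per-frame descriptors capture leg extension:

* **Effective leg length (ELL)** — the chord distance from the trochanter
  to the tarsal claw divided by the summed lengths of the three leg
  segments.  Values close to 1 mean a fully extended leg.
* **Leg joint angle (theta)** — the interior angle at the femoro-patellar
  joint between the trochanto-femoral and tibio-metatarsal joints, in
  [0, 180] degrees (180 = straight leg).

Tracked joints per leg (profile view, camera-facing side):
trochanto-femoral, femoro-patellar, tibio-metatarsal, tarsal claw.  In a
tracked trial the corresponding point names follow the convention
``<leg>_<joint>``, e.g. ``L3_tarsal_claw``, with legs ``L1``..``L4``
(first to fourth pair) and joints ``trochanter``, ``femoro_patellar``,
``tibio_metatarsal``, ``tarsal_claw``.

The classification logic: the propulsive leg is the one that is last to
leave the platform *and* reaches its maximum ELL after the body's peak
acceleration — its extension is still driving the body when the other
legs are airborne.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateChainError, NoLiftoffError
from .io_tracks import PointTrack, TrackedTrial

log = logging.getLogger(__name__)

__all__ = [
    "JOINT_NAMES",
    "LEG_IDS",
    "LegChain",
    "LegChronology",
    "PropulsiveCall",
    "effective_leg_length",
    "joint_angle_series",
    "detect_leg_liftoff",
    "timing_vs_peak",
    "leg_chronology",
    "classify_propulsive",
]

JOINT_NAMES = ("trochanter", "femoro_patellar", "tibio_metatarsal", "tarsal_claw")
LEG_IDS = ("L1", "L2", "L3", "L4")

#: ELL above 1 + this tolerance is flagged as tracking noise.
ELL_NOISE_TOLERANCE = 0.05


@dataclass
class LegChain:
    """One tracked leg: four joint tracks plus reference segment lengths."""

    leg_id: str
    joints: tuple[PointTrack, PointTrack, PointTrack, PointTrack]
    segment_lengths: np.ndarray

    def __post_init__(self) -> None:
        if len(self.joints) != 4:
            raise ValueError("a leg chain has exactly 4 joint tracks")
        lengths = {j.n_frames for j in self.joints}
        if len(lengths) > 1:
            raise ValueError("joint tracks disagree on frame count")
        self.segment_lengths = np.asarray(self.segment_lengths, dtype=float)
        if self.segment_lengths.shape != (3,):
            raise ValueError("need 3 reference segment lengths")
        if not np.all(self.segment_lengths > 0):
            raise ValueError("segment lengths must be > 0")

    @property
    def n_frames(self) -> int:
        return self.joints[0].n_frames

    @property
    def trochanter(self) -> PointTrack:
        return self.joints[0]

    @property
    def claw(self) -> PointTrack:
        return self.joints[3]

    @classmethod
    def from_trial(
        cls,
        trial: TrackedTrial,
        leg_id: str,
        segment_lengths: np.ndarray | None = None,
        percentile: float = 95.0,
    ) -> "LegChain":
        """Assemble a chain from ``<leg>_<joint>`` tracks in a trial.

        When no morphometric segment lengths are supplied they are
        estimated from the tracks themselves as the ``percentile`` of the
        per-frame inter-joint distances (robust to tracking noise).
        """
        joints = []
        for joint in JOINT_NAMES:
            key = f"{leg_id}_{joint}"
            if key not in trial.tracks:
                raise KeyError(f"trial has no track {key!r}")
            joints.append(trial.tracks[key])
        joints = tuple(joints)
        if segment_lengths is None:
            segment_lengths = estimate_segment_lengths(joints, percentile)
        return cls(leg_id=leg_id, joints=joints, segment_lengths=segment_lengths)


def estimate_segment_lengths(
    joints: tuple[PointTrack, ...], percentile: float = 95.0
) -> np.ndarray:
    """Reference segment lengths as a high percentile of per-frame distances."""
    out = np.empty(3)
    for k in range(3):
        d = np.hypot(
            joints[k + 1].x - joints[k].x, joints[k + 1].y - joints[k].y
        )
        d = d[np.isfinite(d)]
        if len(d) == 0:
            raise DegenerateChainError("no finite frames to estimate a segment length")
        out[k] = np.percentile(d, percentile)
    if not np.all(out > 0):
        raise DegenerateChainError("estimated segment length is zero")
    return out


def effective_leg_length(chain: LegChain) -> np.ndarray:
    """Per-frame ELL: trochanter-to-claw chord over summed segment lengths.

    Frames with either endpoint missing yield NaN.  Values slightly above
    1 (tracking noise) are retained; values above 1 + tolerance are
    logged.
    """
    total = float(np.sum(chain.segment_lengths))
    if total <= 0:
        raise DegenerateChainError("segment lengths sum to zero")
    chord = np.hypot(
        chain.claw.x - chain.trochanter.x, chain.claw.y - chain.trochanter.y
    )
    ell = chord / total
    n_over = int(np.sum(ell > 1 + ELL_NOISE_TOLERANCE))
    if n_over:
        log.warning(
            "%s: %d frames with ELL > %.2f (noisy tracking or short reference lengths)",
            chain.leg_id,
            n_over,
            1 + ELL_NOISE_TOLERANCE,
        )
    return ell


def joint_angle_series(chain: LegChain) -> np.ndarray:
    """Per-frame interior angle (deg) at the femoro-patellar joint.

    The angle between the rays from the femoro-patellar joint to the
    trochanto-femoral and tibio-metatarsal joints; 180 deg is a straight
    leg.  Coincident adjacent joints yield NaN with a warning.
    """
    tro, fp, tm = chain.joints[0], chain.joints[1], chain.joints[2]
    v1 = np.column_stack([tro.x - fp.x, tro.y - fp.y])
    v2 = np.column_stack([tm.x - fp.x, tm.y - fp.y])
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    degenerate = (n1 == 0) | (n2 == 0)
    if degenerate.any():
        log.warning(
            "%s: %d frames with coincident adjacent joints; angle set to NaN",
            chain.leg_id,
            int(degenerate.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.sum(v1 * v2, axis=1) / (n1 * n2)
    cosang[degenerate] = np.nan
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def detect_leg_liftoff(
    chain: LegChain,
    platform_y: float,
    height_threshold: float = 0.05,
    persist: int = 3,
) -> int:
    """First frame where the tarsal claw is sustainably above the platform.

    The claw must sit more than ``height_threshold`` mm above the take-off
    surface for ``persist`` consecutive frames.  A leg that is raised for
    the whole trial (legs I/II in a typical jump) lifts off at frame 0.
    """
    if persist < 1:
        raise ValueError("persist must be >= 1")
    above = (chain.claw.y - platform_y) > height_threshold
    above[~np.isfinite(chain.claw.y)] = False
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= persist:
            return i - persist + 1
    raise NoLiftoffError(
        f"{chain.leg_id}: claw never exceeds platform + {height_threshold} mm "
        f"for {persist} frames"
    )


def timing_vs_peak(
    liftoff_frame: int,
    max_ell_frame: int,
    peak_accel_frame: int,
    frame_interval: float,
) -> tuple[float, float]:
    """Signed timing offsets (ms) of lift-off and max ELL vs peak acceleration.

    Positive offsets mean the event happened *after* peak acceleration.
    """
    return (
        (liftoff_frame - peak_accel_frame) * frame_interval,
        (max_ell_frame - peak_accel_frame) * frame_interval,
    )


def first_max_frame(values: np.ndarray, rtol: float = 1e-9) -> int:
    """First frame attaining the series maximum (within a tolerance).

    For series that plateau at full extension this returns the first frame
    of the plateau, not an arbitrary point inside it.
    """
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).any():
        raise DegenerateChainError("series has no finite values")
    vmax = np.nanmax(v)
    tol = abs(vmax) * rtol
    return int(np.nonzero(v >= vmax - tol)[0][0])


@dataclass
class LegChronology:
    """Extension time series and event timing for one leg in one jump."""

    leg_id: str
    ell: np.ndarray
    joint_angle: np.ndarray
    liftoff_frame: int | None
    max_ell_frame: int
    liftoff_minus_peak_ms: float
    max_ell_minus_peak_ms: float
    ell_exceeds_unity: bool = False


def leg_chronology(
    chain: LegChain,
    platform_y: float,
    peak_accel_frame: int,
    frame_interval: float,
    height_threshold: float = 0.05,
    persist: int = 3,
) -> LegChronology:
    """Full chronology for one leg: ELL, joint angle and timing offsets."""
    ell = effective_leg_length(chain)
    theta = joint_angle_series(chain)
    max_ell_frame = first_max_frame(ell)
    try:
        liftoff = detect_leg_liftoff(chain, platform_y, height_threshold, persist)
    except NoLiftoffError:
        liftoff = None
    lo_off, ell_off = timing_vs_peak(
        liftoff if liftoff is not None else peak_accel_frame,
        max_ell_frame,
        peak_accel_frame,
        frame_interval,
    )
    return LegChronology(
        leg_id=chain.leg_id,
        ell=ell,
        joint_angle=theta,
        liftoff_frame=liftoff,
        max_ell_frame=max_ell_frame,
        liftoff_minus_peak_ms=lo_off if liftoff is not None else float("nan"),
        max_ell_minus_peak_ms=ell_off,
        ell_exceeds_unity=bool(np.nanmax(ell) > 1 + ELL_NOISE_TOLERANCE),
    )


@dataclass
class PropulsiveCall:
    """Outcome of propulsive-leg classification with its per-leg rationale."""

    leg_id: str | None
    status: str  # "ok", "conflict" or "inconclusive"
    last_liftoff_leg: str | None
    per_leg: list[dict] = field(default_factory=list)
    note: str = ""


def classify_propulsive(
    chronologies: dict[str, LegChronology], peak_accel_frame: int
) -> PropulsiveCall:
    """Identify the propulsive leg from per-leg chronologies.

    The propulsive leg (a) is the last to leave the platform and (b)
    reaches its maximum ELL after peak acceleration.  When (a) and (b)
    disagree the leg satisfying (b) is returned with a conflict flag; when
    no leg satisfies (b) the call is inconclusive (an explicit status,
    not an error).
    """
    if len(chronologies) < 2:
        raise ValueError("need chronologies for at least 2 legs")
    per_leg = []
    candidates = []
    lifted = []
    for leg_id in sorted(chronologies):
        c = chronologies[leg_id]
        after = c.max_ell_frame > peak_accel_frame
        per_leg.append(
            {
                "leg_id": leg_id,
                "liftoff_frame": c.liftoff_frame,
                "max_ell_frame": c.max_ell_frame,
                "max_ell_after_peak": after,
                "liftoff_minus_peak_ms": c.liftoff_minus_peak_ms,
                "max_ell_minus_peak_ms": c.max_ell_minus_peak_ms,
            }
        )
        if c.liftoff_frame is not None:
            lifted.append((c.liftoff_frame, leg_id))
        if after:
            candidates.append(leg_id)

    last_leg = max(lifted)[1] if lifted else None
    if not candidates:
        return PropulsiveCall(
            leg_id=None,
            status="inconclusive",
            last_liftoff_leg=last_leg,
            per_leg=per_leg,
            note="no leg reached its maximum ELL after peak acceleration",
        )
    # among (b)-satisfying legs prefer the one lifting off last
    def lift_key(leg: str) -> int:
        lo = chronologies[leg].liftoff_frame
        return lo if lo is not None else -1

    chosen = max(candidates, key=lift_key)
    if last_leg is not None and chosen != last_leg:
        return PropulsiveCall(
            leg_id=chosen,
            status="conflict",
            last_liftoff_leg=last_leg,
            per_leg=per_leg,
            note=(
                f"{chosen} peaked ELL after peak acceleration but "
                f"{last_leg} was last to lift off"
            ),
        )
    return PropulsiveCall(
        leg_id=chosen, status="ok", last_liftoff_leg=last_leg, per_leg=per_leg
    )
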