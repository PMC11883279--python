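"""Reading and writing digitized point-track files, trial metadata and results.

The pipeline's universal input is a *tracked trial*: a set of named 2-D point
tracks (one row per video frame) produced by manual frame-by-frame
digitization of high-speed footage, plus the trial metadata needed to
calibrate it (frame rate, mm-per-pixel scale, sex, body mass, platform
geometry).

File dialect
------------
Tracked points live in a flat, wide CSV with one paired column per point and
axis: ``<name>_X``, ``<name>_Y`` (pixel units, one data row per frame).
Untracked cells are left blank.  This is the common export shape of
single-camera video digitizers.  Trial metadata is a plain ``key: value``
text file with the keys ``frame_rate_hz``, ``scale_mm_per_px``, ``sex``,
``body_mass_mg``, ``platform_y_px``, ``gap_mm``, ``subject_id`` and
``trial_id``.

Coordinate convention
---------------------
World coordinates are in millimetres with *x* increasing from the take-off
platform toward the landing platform and *y* increasing upward.  Raw video
files may use image coordinates (y down); pass ``flip_y=True`` to the reader
and the flip is recorded in the trial's provenance.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    CalibrationError,
    EmptyTrackError,
    FormatError,
)

log = logging.getLogger(__name__)

__all__ = [
    "PointTrack",
    "TrialMeta",
    "TrackedTrial",
    "read_tracks_csv",
    "write_tracks_csv",
    "read_meta",
    "write_meta",
    "calibrate_scale",
    "write_results_table",
    "read_results_table",
    "RESULT_COLUMNS",
]


@dataclass
class PointTrack:
    """A single named point digitized over all frames of one trial.

    Coordinates are in millimetres in the world frame.  Frames where the
    point could not be digitized are NaN in both axes.
    """

    name: str
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.y.ndim != 1 or len(self.x) != len(self.y):
            raise ValueError(f"track {self.name!r}: x and y must be equal-length 1-D arrays")
        if len(self.x) < 2:
            raise ValueError(f"track {self.name!r}: needs at least 2 frames")
        if np.isinf(self.x).any() or np.isinf(self.y).any():
            raise ValueError(f"track {self.name!r}: infinite coordinates are not allowed")
        if not np.any(np.isfinite(self.x) & np.isfinite(self.y)):
            raise EmptyTrackError(f"track {self.name!r}: no finite frames")

    @property
    def n_frames(self) -> int:
        return len(self.x)

    def finite_mask(self) -> np.ndarray:
        """Boolean mask of frames where both coordinates are finite."""
        return np.isfinite(self.x) & np.isfinite(self.y)

    def positions(self) -> np.ndarray:
        """(n_frames, 2) array of xy positions."""
        return np.column_stack([self.x, self.y])


@dataclass
class TrialMeta:
    """Calibration and biological metadata for one recorded jump.

    frame_interval : ms between consecutive frames (0.2 ms at 5000 fps)
    scale          : mm per pixel
    sex            : "male" or "female"
    body_mass      : mg
    platform_y     : world y of the take-off surface (mm)
    gap            : horizontal distance to the landing platform (mm)
    """

    frame_interval: float
    scale: float
    sex: str
    body_mass: float
    platform_y: float
    gap: float
    trial_id: str = "trial"
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        for name in ("frame_interval", "scale", "body_mass", "gap"):
            if not getattr(self, name) > 0:
                raise ValueError(f"TrialMeta.{name} must be > 0")
        if self.sex not in ("male", "female"):
            raise ValueError(f"TrialMeta.sex must be 'male' or 'female', got {self.sex!r}")

    @property
    def frame_rate_hz(self) -> float:
        return 1000.0 / self.frame_interval


@dataclass
class TrackedTrial:
    """A calibrated trial: metadata plus all point tracks keyed by name."""

    meta: TrialMeta
    tracks: dict[str, PointTrack]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {t.n_frames for t in self.tracks.values()}
        if len(lengths) > 1:
            raise ValueError(f"tracks disagree on frame count: {sorted(lengths)}")

    @property
    def frame_count(self) -> int:
        return next(iter(self.tracks.values())).n_frames

    @property
    def com(self) -> PointTrack:
        try:
            return self.tracks["CoM"]
        except KeyError:
            raise EmptyTrackError("trial has no 'CoM' track") from None


def calibrate_scale(
    p1: Sequence[float], p2: Sequence[float], known_length: float
) -> float:
    """mm-per-pixel scale from two pixel points a known distance apart.

    An object of printed length in the frame (e.g. the take-off platform)
    serves as the in-frame ruler.
    """
    if known_length <= 0:
        raise ValueError("known_length must be > 0")
    d = math.hypot(p2[0] - p1[0], p2[1] - p1[1])
    if d == 0:
        raise CalibrationError("calibration points coincide")
    return known_length / d


def _interpolate_gaps(values: np.ndarray, max_gap: int, label: str) -> np.ndarray:
    """Linearly fill interior NaN runs of length <= max_gap; log a warning."""
    out = values.copy()
    isnan = ~np.isfinite(out)
    if not isnan.any():
        return out
    n = len(out)
    i = 0
    while i < n:
        if isnan[i]:
            j = i
            while j < n and isnan[j]:
                j += 1
            interior = i > 0 and j < n
            if interior and (j - i) <= max_gap:
                t = np.arange(i, j)
                out[i:j] = np.interp(t, [i - 1, j], [out[i - 1], out[j]])
                log.warning(
                    "%s: interpolated %d-frame gap at frames %d-%d", label, j - i, i, j - 1
                )
            i = j
        else:
            i += 1
    return out


def read_tracks_csv(
    path: str | Path,
    meta: TrialMeta,
    *,
    flip_y: bool = False,
    strict: bool = False,
    max_com_gap: int = 3,
) -> TrackedTrial:
    """Read a digitizer tracked-point CSV into a calibrated trial.

    Pixel coordinates are converted to mm via ``meta.scale``.  With
    ``flip_y`` the image y axis (down) is negated so world y increases
    upward.  Interior gaps of at most ``max_com_gap`` frames in the CoM
    track are linearly interpolated (with a logged warning); longer gaps
    are preserved as missing data.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: cannot parse tracked-point CSV: {exc}") from exc
    if df.shape[0] < 2:
        raise FormatError(f"{path}: fewer than 2 data rows")

    names: list[str] = []
    for col in df.columns:
        if col.endswith("_X"):
            base = col[:-2]
            if f"{base}_Y" not in df.columns:
                raise FormatError(f"{path}: column {col!r} has no matching {base}_Y")
            names.append(base)
        elif col.endswith("_Y"):
            if f"{col[:-2]}_X" not in df.columns:
                raise FormatError(f"{path}: column {col!r} has no matching {col[:-2]}_X")
        elif strict:
            raise FormatError(f"{path}: unknown column {col!r} (strict mode)")
        else:
            log.info("%s: ignoring unrecognized column %r", path, col)
    if not names:
        raise FormatError(f"{path}: no <name>_X/<name>_Y column pairs found")

    ysign = -1.0 if flip_y else 1.0
    tracks: dict[str, PointTrack] = {}
    for name in names:
        x = pd.to_numeric(df[f"{name}_X"], errors="coerce").to_numpy() * meta.scale
        y = pd.to_numeric(df[f"{name}_Y"], errors="coerce").to_numpy() * meta.scale * ysign
        # keep frames jointly finite: a point is either digitized or not
        joint = np.isfinite(x) & np.isfinite(y)
        x[~joint] = np.nan
        y[~joint] = np.nan
        if name == "CoM":
            if not joint.any():
                raise EmptyTrackError(f"{path}: CoM track has zero finite frames")
            x = _interpolate_gaps(x, max_com_gap, f"{path}:CoM.x")
            y = _interpolate_gaps(y, max_com_gap, f"{path}:CoM.y")
        try:
            tracks[name] = PointTrack(name=name, x=x, y=y)
        except EmptyTrackError:
            log.warning("%s: track %r has no finite frames; dropped", path, name)

    prov = {"source": str(path), "flip_y": flip_y, "scale_mm_per_px": meta.scale}
    return TrackedTrial(meta=meta, tracks=tracks, provenance=prov)


def write_tracks_csv(
    trial: TrackedTrial,
    path: str | Path,
    *,
    flip_y: bool = False,
    provenance_comment: str | None = None,
) -> Path:
    """Write a trial back to the tracked-point CSV dialect (pixel units)."""
    path = Path(path)
    ysign = -1.0 if flip_y else 1.0
    data = {}
    for name, tr in trial.tracks.items():
        data[f"{name}_X"] = tr.x / trial.meta.scale
        data[f"{name}_Y"] = tr.y * ysign / trial.meta.scale
    df = pd.DataFrame(data)
    buf = io.StringIO()
    if provenance_comment:
        buf.write(f"# {provenance_comment}\n")
    df.to_csv(buf, index=False, float_format="%.10g")
    path.write_text(buf.getvalue())
    return path


_META_KEYS = (
    "frame_rate_hz",
    "scale_mm_per_px",
    "sex",
    "body_mass_mg",
    "platform_y_px",
    "gap_mm",
    "subject_id",
    "trial_id",
)


def read_meta(path: str | Path, *, flip_y: bool = False) -> TrialMeta:
    """Read a plain key-value trial-metadata file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: cannot parse metadata: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise FormatError(f"{path}: metadata must be key: value lines")
    missing = [k for k in _META_KEYS[:6] if k not in raw]
    if missing:
        raise FormatError(f"{path}: missing metadata keys {missing}")
    scale = float(raw["scale_mm_per_px"])
    ysign = -1.0 if flip_y else 1.0
    return TrialMeta(
        frame_interval=1000.0 / float(raw["frame_rate_hz"]),
        scale=scale,
        sex=str(raw["sex"]),
        body_mass=float(raw["body_mass_mg"]),
        platform_y=float(raw["platform_y_px"]) * scale * ysign,
        gap=float(raw["gap_mm"]),
        subject_id=str(raw.get("subject_id", "subject")),
        trial_id=str(raw.get("trial_id", "trial")),
    )


def write_meta(meta: TrialMeta, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        f"frame_rate_hz: {meta.frame_rate_hz:.10g}",
        f"scale_mm_per_px: {meta.scale:.10g}",
        f"sex: {meta.sex}",
        f"body_mass_mg: {meta.body_mass:.10g}",
        f"platform_y_px: {meta.platform_y / meta.scale:.10g}",
        f"gap_mm: {meta.gap:.10g}",
        f"subject_id: {meta.subject_id}",
        f"trial_id: {meta.trial_id}",
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


#: Fixed column order of the per-jump results table; units are embedded in
#: the column names.
RESULT_COLUMNS = (
    "trial_id",
    "subject_id",
    "sex",
    "body_mass_mg",
    "takeoff_duration_ms",
    "takeoff_velocity_m_per_s",
    "peak_acceleration_m_per_s2",
    "kinetic_energy_uJ",
    "jump_force_mN",
    "jump_power_mW",
    "g_force",
    "takeoff_angle_deg",
    "peak_height_mm",
    "end_height_mm",
)


def write_results_table(
    results: Iterable,
    path: str | Path,
    *,
    provenance_comment: str | None = None,
) -> Path:
    """Write KinematicsResult records as a CSV with a fixed column order."""
    rows = [r.as_row() if hasattr(r, "as_row") else dict(r) for r in results]
    if not rows:
        raise ValueError("cannot write an empty results table")
    df = pd.DataFrame(rows)
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[list(RESULT_COLUMNS)]
    path = Path(path)
    buf = io.StringIO()
    if provenance_comment:
        buf.write(f"# {provenance_comment}\n")
    df.to_csv(buf, index=False, float_format="%.10g")
    path.write_text(buf.getvalue())
    return path


def read_results_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), comment="#")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: results table missing columns {missing}")
    return df
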