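"""Pipeline orchestration: simulate -> analyze -> choreograph -> stats.

A run is driven by a :class:`RunConfig` holding every detection threshold,
statistics option and the master seed.  Outputs are plain CSV/JSON files
whose first comment line embeds the software version and a hash of the
config, so any results file can be traced to the exact settings that
produced it.  Per-trial failures during analysis are isolated, logged and
reported; they do not abort the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .choreography import LEG_IDS, LegChain, classify_propulsive, leg_chronology
from .circstats import circ_summary, watson_williams
from .errors import SaltijumpError, SchemaError
from .group_stats import fit_lmm, mann_whitney, select_model
from .io_tracks import (
    read_meta,
    read_results_table,
    read_tracks_csv,
    write_meta,
    write_results_table,
    write_tracks_csv,
)
from .kinematics import (
    JumpEvents,
    acceleration_series,
    detect_onset,
    detect_takeoff_end,
    peak_acceleration_frame,
    takeoff_metrics,
    velocity_series,
)
from .synthetic import simulate_study

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunSummary", "run_simulate", "run_analyze", "run_report"]


@dataclass
class RunConfig:
    """All knobs of one pipeline run, with documented defaults."""

    # onset detection
    onset_k: float = 3.0
    onset_persist: int = 5
    onset_baseline_frames: int = 50
    # leg lift-off detection
    liftoff_height_mm: float = 0.05
    liftoff_persist: int = 3
    # differentiation
    smooth_window: int = 1
    # statistics
    log_transform: bool = True
    with_interaction: bool = True
    # simulation
    n_male_subjects: int = 10
    n_female_subjects: int = 12
    jumps_per_subject: int = 3
    noise_sd: float = 0.0
    # run
    seed: int = 0
    out_dir: str = "saltijump_run"

    def __post_init__(self) -> None:
        if not (0 < self.onset_k <= 20):
            raise ValueError("onset_k must be in (0, 20]")
        if self.onset_persist < 1 or self.liftoff_persist < 1:
            raise ValueError("persist thresholds must be >= 1")
        if self.liftoff_height_mm < 0:
            raise ValueError("liftoff_height_mm must be >= 0")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def provenance(self) -> str:
        return f"saltijump {__version__} config={self.config_hash()} seed={self.seed}"


@dataclass
class RunSummary:
    n_ok: int
    n_failed: int
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def exit_code(self) -> int:
        if self.n_ok == 0:
            return 2
        return 1 if self.n_failed else 0


def run_simulate(config: RunConfig, out_dir: str | Path | None = None) -> RunSummary:
    """Generate a synthetic study and write trial CSVs, metadata and truth."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials = simulate_study(
        n_male_subjects=config.n_male_subjects,
        n_female_subjects=config.n_female_subjects,
        jumps_per_subject=config.jumps_per_subject,
        seed=config.seed,
        noise_sd=config.noise_sd,
    )
    prov = config.provenance()
    for trial, truth in trials:
        stem = trial.meta.trial_id
        write_tracks_csv(trial, out / f"{stem}.csv", provenance_comment=prov)
        write_meta(trial.meta, out / f"{stem}.meta")
        truth_rows = {
            "onset_frame": truth.onset_frame,
            "abdomen_touch_frame": truth.abdomen_touch_frame,
            "all_legs_off_frame": truth.all_legs_off_frame,
            "peak_accel_frame": truth.peak_accel_frame,
            **{f"liftoff_{k}": v for k, v in truth.liftoff_frames.items()},
            "v_max": truth.v_max,
            "a_peak": truth.a_peak,
            "takeoff_angle": truth.takeoff_angle,
            "takeoff_duration_ms": truth.takeoff_duration,
        }
        pd.DataFrame([truth_rows]).to_csv(out / f"{stem}.truth.csv", index=False)
    (out / "run.json").write_text(
        json.dumps(
            {"version": __version__, "config": dataclasses.asdict(config), "n_trials": len(trials)},
            indent=2,
        )
    )
    log.info("wrote %d simulated trials to %s", len(trials), out)
    return RunSummary(n_ok=len(trials), n_failed=0)


def detect_events(trial, config: RunConfig) -> JumpEvents:
    """Detect the full event set for one trial.

    Onset comes from the CoM noise floor; per-leg lift-offs from the claw
    heights when leg tracks are present, in which case all-legs-off is the
    latest lift-off; otherwise the end of stance is estimated from the
    first sustained non-positive path acceleration after the peak.
    """
    com = trial.com
    onset, sigma = detect_onset(
        com, config.onset_baseline_frames, config.onset_k, config.onset_persist
    )
    speed = velocity_series(com, trial.meta.frame_interval, config.smooth_window)
    accel = acceleration_series(speed, trial.meta.frame_interval)
    liftoffs: dict[str, int | None] = {}
    stance_liftoffs = []
    for leg_id in LEG_IDS:
        try:
            chain = LegChain.from_trial(trial, leg_id)
        except KeyError:
            continue
        try:
            from .choreography import detect_leg_liftoff

            lo = detect_leg_liftoff(
                chain,
                trial.meta.platform_y,
                config.liftoff_height_mm,
                config.liftoff_persist,
            )
            liftoffs[leg_id] = lo
            if lo > onset:  # a leg that was on the platform during stance
                stance_liftoffs.append(lo)
        except SaltijumpError as exc:
            log.warning("%s: %s", trial.meta.trial_id, exc)
            liftoffs[leg_id] = None
    if stance_liftoffs:
        all_off = max(stance_liftoffs)
    else:
        peak0 = peak_acceleration_frame(accel, onset)
        all_off = detect_takeoff_end(accel, peak0 - 1)
        log.info(
            "%s: no leg tracks; all-legs-off estimated from acceleration sign", trial.meta.trial_id
        )
    # restrict the acceleration-peak search to the take-off window
    j0, j1 = max(onset - 1, 0), max(all_off - 1, 1)
    peak_frame = int(np.nanargmax(accel[j0:j1])) + j0 + 1
    return JumpEvents(
        onset_frame=onset,
        abdomen_move_frame=max(onset - 1, 0),
        all_legs_off_frame=all_off,
        peak_accel_frame=peak_frame,
        per_leg_liftoff=liftoffs,
        onset_noise_floor=sigma,
    )


def analyze_trial(trial, config: RunConfig):
    """Events, kinematic panel and per-leg chronologies for one trial."""
    events = detect_events(trial, config)
    result = takeoff_metrics(trial, events, config.smooth_window)
    chronologies = {}
    for leg_id in LEG_IDS:
        try:
            chain = LegChain.from_trial(trial, leg_id)
        except KeyError:
            continue
        chronologies[leg_id] = leg_chronology(
            chain,
            trial.meta.platform_y,
            events.peak_accel_frame,
            trial.meta.frame_interval,
            config.liftoff_height_mm,
            config.liftoff_persist,
        )
    call = (
        classify_propulsive(chronologies, events.peak_accel_frame)
        if len(chronologies) >= 2
        else None
    )
    return events, result, chronologies, call


def run_analyze(
    tracks_dir: str | Path, config: RunConfig, out_dir: str | Path | None = None
) -> RunSummary:
    """Analyze every trial CSV in a directory; write results and chronology."""
    tracks_dir = Path(tracks_dir)
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trial_files = sorted(
        p for p in tracks_dir.glob("*.csv") if not p.name.endswith(".truth.csv")
    )
    results, chron_rows, event_rows = [], [], []
    failures: dict[str, str] = {}
    for path in trial_files:
        meta_path = path.with_suffix(".meta")
        try:
            meta = read_meta(meta_path) if meta_path.exists() else None
            if meta is None:
                raise SchemaError(f"no metadata file {meta_path.name}")
            trial = read_tracks_csv(path, meta)
            events, result, chronologies, call = analyze_trial(trial, config)
        except (SaltijumpError, ValueError, KeyError) as exc:
            log.error("trial %s failed: %s", path.name, exc)
            failures[path.name] = str(exc)
            continue
        results.append(result)
        dt = meta.frame_interval
        event_rows.append(
            {
                "trial_id": meta.trial_id,
                "onset_frame": events.onset_frame,
                "onset_ms": events.onset_frame * dt,
                "all_legs_off_frame": events.all_legs_off_frame,
                "all_legs_off_ms": events.all_legs_off_frame * dt,
                "peak_accel_frame": events.peak_accel_frame,
                "peak_accel_ms": events.peak_accel_frame * dt,
                "onset_noise_floor_mm": events.onset_noise_floor,
            }
        )
        for leg_id, c in chronologies.items():
            chron_rows.append(
                {
                    "trial_id": meta.trial_id,
                    "subject_id": meta.subject_id,
                    "sex": meta.sex,
                    "leg_id": leg_id,
                    "liftoff_frame": c.liftoff_frame,
                    "liftoff_ms": (
                        c.liftoff_frame * dt if c.liftoff_frame is not None else np.nan
                    ),
                    "liftoff_minus_peak_ms": c.liftoff_minus_peak_ms,
                    "max_ell_minus_peak_ms": c.max_ell_minus_peak_ms,
                    "max_ell": float(np.nanmax(c.ell)),
                    "propulsive_call": call.leg_id if call else None,
                    "propulsive_status": call.status if call else None,
                }
            )
    if not results:
        raise SaltijumpError(f"zero analyzable trials in {tracks_dir}")
    prov = config.provenance()
    write_results_table(results, out / "results.csv", provenance_comment=prov)
    with open(out / "chronology.csv", "w") as fh:
        fh.write(f"# {prov}\n")
        pd.DataFrame(chron_rows).to_csv(fh, index=False, float_format="%.10g")
    with open(out / "events.csv", "w") as fh:
        fh.write(f"# {prov}\n")
        pd.DataFrame(event_rows).to_csv(fh, index=False, float_format="%.10g")
    summary = RunSummary(n_ok=len(results), n_failed=len(failures), failures=failures)
    (out / "analyze.json").write_text(
        json.dumps(
            {
                "version": __version__,
                "config": dataclasses.asdict(config),
                "n_ok": summary.n_ok,
                "failures": failures,
            },
            indent=2,
        )
    )
    return summary


#: Kinematic responses modelled in the group-statistics report.
REPORT_RESPONSES = (
    "takeoff_velocity_m_per_s",
    "peak_acceleration_m_per_s2",
    "kinetic_energy_uJ",
    "jump_force_mN",
    "jump_power_mW",
    "takeoff_duration_ms",
    "g_force",
)


def kinematic_panel(results: pd.DataFrame) -> pd.DataFrame:
    """Sex-wise means of the per-jump panel (angles summarized circularly)."""
    needed = {"sex", "takeoff_angle_deg"}
    if not needed <= set(results.columns):
        raise SchemaError(f"results table missing {sorted(needed - set(results.columns))}")
    rows = {}
    for sex, grp in results.groupby("sex"):
        row = {
            "n_jumps": len(grp),
            "body_mass_mg": grp["body_mass_mg"].mean(),
        }
        for col in REPORT_RESPONSES:
            row[col] = grp[col].mean()
        summ = circ_summary(grp["takeoff_angle_deg"].dropna())
        angle = summ.mean_angle
        row["takeoff_angle_deg"] = angle - 360.0 if angle > 180 else angle
        row["takeoff_angle_circ_sd_deg"] = summ.circular_sd_deg
        row["takeoff_angle_r"] = summ.r
        rows[sex] = row
    return pd.DataFrame(rows).T


def run_report(
    results: str | Path | pd.DataFrame, config: RunConfig, out_dir: str | Path | None = None
) -> dict:
    """Summary tables: sex panel, circular test and per-response mixed models."""
    if isinstance(results, (str, Path)):
        path = Path(results)
        if path.is_dir():
            path = path / "results.csv"
        results = read_results_table(path)
    panel = kinematic_panel(results)

    report: dict = {"panel": panel}
    sexes = sorted(results["sex"].unique())
    if len(sexes) == 2:
        a = results.loc[results["sex"] == sexes[0], "takeoff_angle_deg"].dropna()
        b = results.loc[results["sex"] == sexes[1], "takeoff_angle_deg"].dropna()
        if len(a) >= 2 and len(b) >= 2:
            report["takeoff_angle_test"] = watson_williams(a, b)
        mass = results.groupby("subject_id").agg(
            sex=("sex", "first"), body_mass_mg=("body_mass_mg", "first")
        )
        report["body_mass_test"] = mann_whitney(
            mass.loc[mass["sex"] == sexes[0], "body_mass_mg"],
            mass.loc[mass["sex"] == sexes[1], "body_mass_mg"],
        )
        models = {}
        for response in REPORT_RESPONSES:
            if response not in results.columns or results[response].isna().any():
                continue
            try:
                full = fit_lmm(results, response, True, config.log_transform)
                reduced = fit_lmm(results, response, False, config.log_transform)
                selected, delta = select_model(full, reduced)
                models[response] = {
                    "selected": selected,
                    "delta_aic": delta,
                    "coefficients": selected.coefficient_table(),
                    "anova": selected.ftable,
                }
            except SaltijumpError as exc:
                log.warning("model for %s skipped: %s", response, exc)
        report["models"] = models

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        prov = config.provenance()
        with open(out / "panel.csv", "w") as fh:
            fh.write(f"# {prov}\n")
            panel.to_csv(fh, float_format="%.6g")
        lines = [f"# {prov}"]
        if "takeoff_angle_test" in report:
            ww = report["takeoff_angle_test"]
            lines.append(
                f"Watson-Williams take-off angle: F({ww.df1},{ww.df2}) = {ww.F:.3f}, "
                f"p = {ww.p:.4f}" + (f"  [{'; '.join(ww.flags)}]" if ww.flags else "")
            )
        if "body_mass_test" in report:
            mw = report["body_mass_test"]
            lines.append(f"Mann-Whitney body mass: U = {mw.U:.1f}, p = {mw.p:.4g} ({mw.method})")
        for response, m in report.get("models", {}).items():
            sel = m["selected"]
            lines.append(
                f"\n== {response} (log={sel.log_transformed}, "
                f"interaction={'kept' if sel.with_interaction else 'dropped'}, "
                f"dAIC={m['delta_aic']:+.2f}, den.df method={sel.denominator_df_method}) =="
            )
            lines.append(m["coefficients"].to_string(float_format=lambda v: f"{v:.4g}"))
            if len(m["anova"]):
                lines.append("Type III ANOVA:")
                lines.append(m["anova"].to_string(float_format=lambda v: f"{v:.4g}"))
        (out / "stats_report.txt").write_text("\n".join(lines) + "\n")
    return report
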