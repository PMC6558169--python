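"""Per-trial and per-subject behavioural metrics.

Latency, peak velocity, amplitude, duration, and gain per accepted
primary saccade and eye; anti-saccade correctness and performance (the
percentage of correctly performed trials among all adequate trials);
pro- vs anti-saccade task differences in latency and peak velocity,
including the amplitude-scaled variant; and tidy cohort tables.

Conventions: gain is the signed ratio of final eye position to the
target position (mirror of the target for anti-saccades); a leftward
movement of the left eye is abduction and of the right eye adduction,
mirrored for rightward movements; a correct anti-saccade moves opposite
the target side.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .config import StudyConfig
from .detection import events_table
from .qc import accept_condition
from .records import EYES, TrialRecord

CONDITION_KEYS = ["task", "direction", "eccentricity"]


def movement_type(eye: str, saccade_direction: str) -> str:
    """Abduction (away from the nose) or adduction (toward it)."""
    if eye not in EYES or saccade_direction not in ("left", "right"):
        raise ValueError("eye and saccade_direction must be 'left' or 'right'")
    return "abduction" if eye == saccade_direction else "adduction"


def compute_gain(event, trial: TrialRecord) -> float:
    """Signed ratio of the eye's final position to the reference position.

    Reference = target position for prosaccades; its mirror for
    anti-saccades (the instructed landing side).
    """
    reference = trial.target_deg if trial.task == "prosaccade" else -trial.target_deg
    if reference == 0:
        raise ValueError("zero target reference")
    return float(event.final_position_deg) / reference


def antisaccade_correct(event, trial: TrialRecord) -> bool:
    """Primary saccade direction opposite the target side."""
    if trial.task != "antisaccade":
        raise ValueError("correctness is defined for anti-saccade trials only")
    return event.direction != trial.direction


def trial_metrics(trials: Sequence[TrialRecord],
                  config: StudyConfig | None = None,
                  events: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-trial, per-eye metric table over a QC'ed cohort.

    One row per (trial, eye). ``adequate`` marks trials whose eye has an
    accepted primary saccade; metric columns are NaN otherwise (flagged
    missing, never silently dropped). Pass a precomputed ``events`` table
    to skip re-running detection.
    """
    config = config or StudyConfig()
    if events is None:
        events = events_table(trials, config)
    meta = {t.key(): t for t in trials}
    rows = []
    primaries = events[events["primary"]].set_index(
        ["subject_id", "task", "direction", "eccentricity", "trial_index", "eye"])
    for trial in trials:
        subject_id, task, direction, eccentricity, trial_index = trial.key()
        for eye in EYES:
            key = (subject_id, task, direction, eccentricity, trial_index, eye)
            row = {
                "subject_id": subject_id, "group": trial.group, "task": task,
                "direction": direction, "eccentricity": eccentricity,
                "trial_index": trial_index, "eye": eye,
                "adequate": False, "latency_ms": np.nan,
                "peak_velocity_deg_s": np.nan, "amplitude_deg": np.nan,
                "duration_ms": np.nan, "gain": np.nan,
                "saccade_direction": None, "movement_type": None,
                "correct": np.nan,
            }
            if key in primaries.index:
                ev = primaries.loc[key]

                class _Ev:  # adapter for compute_gain/antisaccade_correct
                    direction = ev["saccade_direction"]
                    final_position_deg = ev["final_position_deg"]

                row.update({
                    "adequate": True,
                    "latency_ms": ev["onset_ms"],
                    "peak_velocity_deg_s": ev["peak_velocity_deg_s"],
                    "amplitude_deg": ev["amplitude_deg"],
                    "duration_ms": ev["duration_ms"],
                    "gain": compute_gain(_Ev, meta[trial.key()]),
                    "saccade_direction": ev["saccade_direction"],
                    "movement_type": movement_type(eye, ev["saccade_direction"]),
                    "correct": (antisaccade_correct(_Ev, meta[trial.key()])
                                if task == "antisaccade" else np.nan),
                })
            rows.append(row)
    return pd.DataFrame(rows)


def antisaccade_performance(subject_trials: pd.DataFrame,
                            eye: str = "left") -> float:
    """Percent correct among adequate anti-saccade trials of one subject.

    Correctness is taken from the given eye's primary saccade (falling
    back to the other eye when that eye is inadequate). NaN (flagged
    undefined) when no trial is adequate.
    """
    anti = subject_trials[subject_trials["task"] == "antisaccade"]
    if anti.empty:
        return float("nan")
    other = "right" if eye == "left" else "left"
    per_trial = []
    trial_keys = ["direction", "eccentricity", "trial_index"]
    for _, grp in anti.groupby(trial_keys, sort=False):
        preferred = grp[grp["eye"] == eye]
        fallback = grp[grp["eye"] == other]
        use = preferred if (not preferred.empty
                            and bool(preferred["adequate"].iloc[0])) else fallback
        if use.empty or not bool(use["adequate"].iloc[0]):
            continue
        per_trial.append(bool(use["correct"].iloc[0]))
    if not per_trial:
        return float("nan")
    return 100.0 * sum(per_trial) / len(per_trial)


def condition_summary(metrics: pd.DataFrame,
                      config: StudyConfig | None = None) -> pd.DataFrame:
    """Mean latency/peak velocity/gain per subject, task, condition, eye.

    ``n_trials`` counts adequate trials; ``condition_accepted`` applies
    the at-least-9 rule to that count.
    """
    config = config or StudyConfig()
    keys = ["subject_id", "group", *CONDITION_KEYS, "eye"]
    rows = []
    for key, grp in metrics.groupby(keys, sort=True):
        ok = grp[grp["adequate"]]
        rows.append({
            **dict(zip(keys, key)),
            "n_trials": int(len(ok)),
            "condition_accepted": accept_condition(ok, config),
            "latency_ms": ok["latency_ms"].mean(),
            "peak_velocity_deg_s": ok["peak_velocity_deg_s"].mean(),
            "gain": ok["gain"].mean(),
        })
    return pd.DataFrame(rows)


def task_differences(subject_metrics: pd.DataFrame,
                     config: StudyConfig | None = None) -> dict:
    """Pro- vs anti-saccade differences for one subject's trial table.

    latency_difference_ms = mean anti-saccade latency - mean prosaccade
    latency; peak_velocity_difference_deg_s = mean prosaccade PV - mean
    anti-saccade PV; the scaled variant divides each trial's PV by its
    amplitude before averaging (zero-amplitude trials are skipped with a
    warning). All three are NaN when either task has no adequate trial.
    """
    config = config or StudyConfig()
    eye = config.analysis_eye
    rows = subject_metrics[(subject_metrics["eye"] == eye)
                           & subject_metrics["adequate"]]
    out = {"latency_difference_ms": float("nan"),
           "peak_velocity_difference_deg_s": float("nan"),
           "scaled_peak_velocity_difference": float("nan")}
    pro = rows[rows["task"] == "prosaccade"]
    anti = rows[rows["task"] == "antisaccade"]
    if pro.empty or anti.empty:
        return out
    out["latency_difference_ms"] = float(anti["latency_ms"].mean()
                                         - pro["latency_ms"].mean())
    out["peak_velocity_difference_deg_s"] = float(
        pro["peak_velocity_deg_s"].mean() - anti["peak_velocity_deg_s"].mean())

    def scaled(frame: pd.DataFrame) -> float:
        amp = frame["amplitude_deg"].to_numpy()
        pv = frame["peak_velocity_deg_s"].to_numpy()
        keep = amp != 0
        if not keep.all():
            warnings.warn("zero-amplitude trial skipped from scaled peak "
                          "velocity", stacklevel=2)
        return float(np.mean(pv[keep] / amp[keep])) if keep.any() else float("nan")

    out["scaled_peak_velocity_difference"] = scaled(pro) - scaled(anti)
    return out


def subject_summary(metrics: pd.DataFrame,
                    config: StudyConfig | None = None) -> pd.DataFrame:
    """One row per subject: anti-saccade performance and task differences."""
    config = config or StudyConfig()
    rows = []
    for (subject_id, group), grp in metrics.groupby(["subject_id", "group"],
                                                    sort=True):
        rows.append({
            "subject_id": subject_id, "group": group,
            "antisaccade_performance_pct": antisaccade_performance(
                grp, config.analysis_eye),
            **task_differences(grp, config),
        })
    return pd.DataFrame(rows, columns=[
        "subject_id", "group", "antisaccade_performance_pct",
        "latency_difference_ms", "peak_velocity_difference_deg_s",
        "scaled_peak_velocity_difference"])


def cohort_summary(condition_means: pd.DataFrame) -> pd.DataFrame:
    """Long-format cohort table with deterministic ordering.

    One row per subject x task x condition x eye x metric, with the
    movement type implied by eye and target direction.
    """
    metric_names = ["latency_ms", "peak_velocity_deg_s", "gain"]
    columns = ["subject_id", "group", "task", "direction", "eccentricity",
               "eye", "movement_type", "metric", "value"]
    if condition_means.empty:
        return pd.DataFrame(columns=columns)
    long = condition_means.melt(
        id_vars=["subject_id", "group", "task", "direction", "eccentricity",
                 "eye"],
        value_vars=metric_names, var_name="metric", value_name="value")
    # instructed movement: toward the target (prosaccade) or its mirror
    mirror = {"left": "right", "right": "left"}
    long["movement_type"] = [
        movement_type(e, d if task == "prosaccade" else mirror[d])
        for e, d, task in zip(long["eye"], long["direction"], long["task"])]
    long = long[columns].sort_values(
        ["subject_id", "task", "direction", "eccentricity", "eye", "metric"],
        kind="stable").reset_index(drop=True)
    return long
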