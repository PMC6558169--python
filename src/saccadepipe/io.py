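"""Reading and writing the long-format gaze CSV dialect, plus geometry.

One row per binocular sample with header
``subject_id, group, task, direction, eccentricity, trial_index, t_ms,
x_left, y_left, valid_left, x_right, y_right, valid_right``; unknown
columns are carried through untouched. Positions are degrees of visual
angle (rightward positive), time is milliseconds from stimulus onset.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import (
    ECCENTRICITY_DEG,
    GazeDataError,
    GazeFormatError,
    TrialRecord,
    sort_key,
)

META_COLUMNS = ["subject_id", "group", "task", "direction", "eccentricity",
                "trial_index"]
SAMPLE_COLUMNS = ["t_ms", "x_left", "y_left", "valid_left",
                  "x_right", "y_right", "valid_right"]
GAZE_COLUMNS = META_COLUMNS + SAMPLE_COLUMNS


def read_gaze_table(path: str | Path) -> list[TrialRecord]:
    """Parse a gaze CSV into one TrialRecord per (subject, task, condition,
    trial_index), samples sorted by time.

    Raises GazeFormatError naming the first missing mandatory column, and
    GazeDataError identifying a trial whose sample times are not strictly
    increasing.
    """
    # round_trip parser: shortest-repr floats written by to_csv come back
    # bit-identical, making write -> read the identity
    frame = pd.read_csv(path, float_precision="round_trip")
    for col in GAZE_COLUMNS:
        if col not in frame.columns:
            raise GazeFormatError(f"{path}: missing mandatory column {col!r}")
    extra_cols = [c for c in frame.columns if c not in GAZE_COLUMNS]
    trials: list[TrialRecord] = []
    for key, rows in frame.groupby(META_COLUMNS, sort=False):
        subject_id, group, task, direction, eccentricity, trial_index = key
        rows = rows.sort_values("t_ms", kind="stable")
        t = rows["t_ms"].to_numpy(dtype=float)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise GazeDataError(
                f"{path}: non-monotone t_ms in trial "
                f"{(subject_id, task, direction, eccentricity, int(trial_index))}"
            )
        extras = {}
        if extra_cols:
            extras["extra_columns"] = {
                c: rows[c].to_numpy() for c in extra_cols
            }
        trials.append(TrialRecord(
            subject_id=str(subject_id), group=str(group), task=str(task),
            direction=str(direction), eccentricity=str(eccentricity),
            trial_index=int(trial_index),
            t_ms=t,
            x_left=rows["x_left"].to_numpy(dtype=float),
            y_left=rows["y_left"].to_numpy(dtype=float),
            valid_left=rows["valid_left"].to_numpy(dtype=int),
            x_right=rows["x_right"].to_numpy(dtype=float),
            y_right=rows["y_right"].to_numpy(dtype=float),
            valid_right=rows["valid_right"].to_numpy(dtype=int),
            extras=extras,
        ))
    return trials


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Long-format frame, rows grouped by subject with trial order preserved."""
    if not trials:
        raise ValueError("cannot serialise an empty trial collection")
    ordered = sorted(trials, key=sort_key)
    parts = []
    for tr in ordered:
        part = pd.DataFrame({
            "subject_id": tr.subject_id, "group": tr.group, "task": tr.task,
            "direction": tr.direction, "eccentricity": tr.eccentricity,
            "trial_index": tr.trial_index,
            "t_ms": tr.t_ms,
            "x_left": tr.x_left, "y_left": tr.y_left,
            "valid_left": tr.valid_left,
            "x_right": tr.x_right, "y_right": tr.y_right,
            "valid_right": tr.valid_right,
        })
        for name, values in tr.extras.get("extra_columns", {}).items():
            part[name] = values
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def write_gaze_table(trials: Sequence[TrialRecord], path: str | Path) -> None:
    """Write trials as the gaze CSV dialect; read_gaze_table round-trips it."""
    trials_to_frame(trials).to_csv(path, index=False)


def screen_offset_to_degrees(offset_cm: float, viewing_distance_cm: float = 60.0):
    """Horizontal screen offset (cm) to degrees of visual angle.

    atan(offset / distance) in degrees; odd and strictly increasing in the
    offset. Vectorised over ``offset_cm``.
    """
    if viewing_distance_cm <= 0:
        raise ValueError("viewing distance must be strictly positive")
    return np.degrees(np.arctan(np.asarray(offset_cm, dtype=float)
                                / viewing_distance_cm))[()]


def degrees_to_screen_offset(angle_deg: float, viewing_distance_cm: float = 60.0):
    """Inverse of screen_offset_to_degrees."""
    if viewing_distance_cm <= 0:
        raise ValueError("viewing distance must be strictly positive")
    return (np.tan(np.radians(np.asarray(angle_deg, dtype=float)))
            * viewing_distance_cm)[()]
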