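"""Trial-level quality control: missing-data exclusion, interpolation,
practice-trial removal, and condition acceptance.

A sample is missing when its tracker validity code exceeds 1. A trial is
excluded when, on either eye (configurable), more than 10% of samples are
missing, more than 100 ms is missing contiguously, or more than 80% of
the first 50 ms is missing — all strict inequalities, boundary cases
retained. Surviving trials have interior gaps filled by linear
interpolation between the nearest valid neighbours; leading/trailing
gaps take the nearest valid value. The first two trials of every
condition are practice and dropped; a condition is accepted with at
least 9 adequate trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import StudyConfig
from .records import EYES, GazeDataError, TrialRecord, VALID_CODE_MAX_USABLE

REASONS = ("frac_gt_10", "gap_gt_100ms", "first50_gt_80", "manual")


@dataclass
class QCReport:
    """Missing-data statistics and the exclusion decision for one trial."""

    trial_key: tuple
    missing_fraction: dict  # eye -> fraction in [0, 1]
    longest_gap_ms: dict  # eye -> ms
    missing_first50_fraction: dict  # eye -> fraction
    excluded: bool
    reasons: list = field(default_factory=list)

    def to_row(self) -> dict:
        subject_id, task, direction, eccentricity, trial_index = self.trial_key
        return {
            "subject_id": subject_id, "task": task, "direction": direction,
            "eccentricity": eccentricity, "trial_index": trial_index,
            **{f"missing_fraction_{e}": self.missing_fraction[e] for e in EYES},
            **{f"longest_gap_ms_{e}": self.longest_gap_ms[e] for e in EYES},
            **{f"missing_first50_fraction_{e}":
               self.missing_first50_fraction[e] for e in EYES},
            "excluded": self.excluded,
            "reasons": ";".join(self.reasons),
        }


def missing_mask(trial: TrialRecord, eye: str) -> np.ndarray:
    """True where the eye's validity code marks the sample unusable (> 1)."""
    return trial.validity(eye) > VALID_CODE_MAX_USABLE


def _longest_run(mask: np.ndarray) -> int:
    if mask.size == 0 or not mask.any():
        return 0
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return int(np.max(edges[1::2] - edges[::2]))


def exclusion_decision(trial: TrialRecord, config: StudyConfig) -> QCReport:
    """Evaluate the three missing-data rules.

    Gap duration is run length x the nominal sample interval (robust to
    timestamp jitter). Per-eye verdicts are OR-combined across eyes by
    default ("and" available via config.qc_eye_mode).
    """
    dt = config.sample_interval_ms
    frac, gap, first50 = {}, {}, {}
    per_eye_reasons = {}
    for eye in EYES:
        mask = missing_mask(trial, eye)
        n = mask.size
        frac[eye] = float(mask.mean()) if n else 0.0
        gap[eye] = _longest_run(mask) * dt
        head = mask[trial.t_ms < config.first50_ms]
        first50[eye] = float(head.mean()) if head.size else 0.0
        reasons = []
        if frac[eye] > config.max_missing_frac:
            reasons.append("frac_gt_10")
        if gap[eye] > config.max_gap_ms:
            reasons.append("gap_gt_100ms")
        if first50[eye] > config.max_missing_first50_frac:
            reasons.append("first50_gt_80")
        per_eye_reasons[eye] = reasons
    if config.qc_eye_mode == "or":
        combined = sorted(set(per_eye_reasons["left"]) | set(per_eye_reasons["right"]),
                          key=REASONS.index)
    else:
        combined = sorted(set(per_eye_reasons["left"]) & set(per_eye_reasons["right"]),
                          key=REASONS.index)
    return QCReport(
        trial_key=trial.key(), missing_fraction=frac, longest_gap_ms=gap,
        missing_first50_fraction=first50,
        excluded=bool(combined), reasons=list(combined),
    )


def interpolate_missing(trial: TrialRecord) -> TrialRecord:
    """Fill missing samples per eye and channel.

    Interior runs take the line between the nearest valid neighbours;
    leading/trailing runs take the nearest valid value. Validity codes are
    left untouched; the fill masks are recorded in
    ``extras["interpolated"]`` as provenance.
    """
    out = trial.copy()
    fills = {}
    for eye in EYES:
        mask = missing_mask(trial, eye)
        fills[eye] = mask.copy()
        if not mask.any():
            continue
        if mask.all():
            raise GazeDataError(
                f"{trial.key()}: no valid samples on the {eye} eye")
        valid_t = trial.t_ms[~mask]
        for channel in ("x", "y"):
            series = (out.x(eye) if channel == "x" else out.y(eye))
            series[mask] = np.interp(trial.t_ms[mask], valid_t, series[~mask])
    out.extras["interpolated"] = fills
    return out


def drop_practice(trials: Iterable[TrialRecord],
                  config: StudyConfig | None = None) -> list[TrialRecord]:
    """Remove the first ``practice_trials`` indices of every condition."""
    cutoff = (config or StudyConfig()).practice_trials
    return [t for t in trials if t.trial_index > cutoff]


def accept_condition(valid_trials: Sequence, config: StudyConfig | None = None) -> bool:
    """At least min_trials_per_condition adequate trials remain."""
    return len(valid_trials) >= (config or StudyConfig()).min_trials_per_condition


def run_qc(
    trials: Sequence[TrialRecord],
    config: StudyConfig | None = None,
    manual_exclusions: Iterable[tuple] | None = None,
) -> tuple[pd.DataFrame, list[TrialRecord]]:
    """QC a cohort: practice drop, exclusion rules, interpolation.

    ``manual_exclusions`` is an optional collection of trial keys excluded
    on visual inspection (reason "manual"). Returns the per-trial QC table
    (practice trials omitted) and the retained, interpolated trials.
    """
    config = config or StudyConfig()
    manual = {tuple(k) for k in (manual_exclusions or [])}
    reports, retained = [], []
    for trial in drop_practice(trials, config):
        report = exclusion_decision(trial, config)
        if trial.key() in manual:
            report.reasons.append("manual")
            report.excluded = True
        reports.append(report.to_row())
        if not report.excluded:
            retained.append(interpolate_missing(trial))
    columns = list(QCReport(("", "", "", "", 0),
                            {e: 0.0 for e in EYES}, {e: 0.0 for e in EYES},
                            {e: 0.0 for e in EYES}, False).to_row())
    return pd.DataFrame(reports, columns=columns), retained
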