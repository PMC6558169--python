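"""End-to-end pipeline: raw trials -> QC -> detection -> metrics -> INO."""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .config import StudyConfig
from .detection import events_table
from .ino import di_table, screen_cohort
from .metrics import (
    cohort_summary,
    condition_summary,
    subject_summary,
    trial_metrics,
)
from .qc import run_qc
from .records import TrialRecord


def analyze_cohort(
    trials: Sequence[TrialRecord],
    config: StudyConfig | None = None,
    manual_exclusions: Iterable[tuple] | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the full analysis on a cohort of raw trials.

    Returns a dict of tidy tables: ``qc`` (per-trial exclusion report),
    ``events`` (every located saccade-like event), ``trial_metrics``
    (per-trial, per-eye metrics), ``condition_means``, ``subjects``
    (performance and task differences), ``cohort`` (long-format means),
    and ``ino`` (DI, Z-scores, screen labels per subject and direction).
    """
    config = config or StudyConfig()
    qc_report, retained = run_qc(trials, config, manual_exclusions)
    events = events_table(retained, config)
    metrics = trial_metrics(retained, config, events=events)
    condition_means = condition_summary(metrics, config)
    subjects = subject_summary(metrics, config)
    ino = screen_cohort(di_table(metrics, config), config)
    return {
        "qc": qc_report,
        "events": events,
        "trial_metrics": metrics,
        "condition_means": condition_means,
        "subjects": subjects,
        "cohort": cohort_summary(condition_means),
        "ino": ino,
    }
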