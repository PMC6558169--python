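"""Analysis configuration: every numeric threshold of the pipeline.

Defaults follow the acquisition and processing protocol the package
implements: 300 Hz sampling, 50 deg/s velocity threshold sustained over 2
consecutive samples, an 11-point Savitzky-Golay filter, a 100-600 ms
latency acceptance window, a 12 ms minimum duration, fixation within 1.5
deg of the cross with < 0.6 deg drift, and the 10% / 100 ms / 80%-in-the-
first-50-ms missing-data exclusion rules. Any field can be overridden from
a flat YAML mapping.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml


@dataclass
class StudyConfig:
    sampling_rate_hz: float = 300.0
    velocity_threshold_deg_s: float = 50.0
    consecutive_points: int = 2
    sg_window: int = 11
    #: Polynomial order of the Savitzky-Golay fit. 6 preserves the peak
    #: velocity and acceleration-zero onset timing of brief saccades under
    #: an 11-point window at 300 Hz; lower orders smooth more aggressively.
    sg_polyorder: int = 6
    onset_search_ms: float = 50.0
    latency_min_ms: float = 100.0
    latency_max_ms: float = 600.0
    min_duration_ms: float = 12.0
    fixation_radius_deg: float = 1.5
    fixation_drift_deg: float = 0.6
    max_missing_frac: float = 0.10
    max_gap_ms: float = 100.0
    max_missing_first50_frac: float = 0.80
    first50_ms: float = 50.0
    practice_trials: int = 2
    min_trials_per_condition: int = 9
    viewing_distance_cm: float = 60.0
    ino_z_margin: float = 2.0
    # -- implementation choices exposed as options -----------------------
    #: "or": a trial is excluded if either eye trips a QC rule (default);
    #: "and": only if both eyes do.
    qc_eye_mode: str = "or"
    #: Signed-velocity level treated as "velocity reached zero" at offset.
    offset_velocity_threshold_deg_s: float = 0.0
    #: Eye whose metrics feed subject-level summaries and task differences.
    analysis_eye: str = "left"
    #: "mean_of_ratios" (default) or "ratio_of_means" per-subject DI.
    di_statistic: str = "mean_of_ratios"
    #: Compute HC Z-scores leaving each control out of its own reference.
    di_leave_one_out: bool = False
    #: Pool left/right DI values before screening instead of per direction.
    ino_pooled: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = (
            "sampling_rate_hz", "velocity_threshold_deg_s", "onset_search_ms",
            "latency_min_ms", "latency_max_ms", "min_duration_ms",
            "fixation_radius_deg", "fixation_drift_deg", "max_missing_frac",
            "max_gap_ms", "max_missing_first50_frac", "first50_ms",
            "viewing_distance_cm", "ino_z_margin",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.sg_window % 2 == 0 or self.sg_window < self.sg_polyorder + 2:
            raise ValueError("sg_window must be odd and >= sg_polyorder + 2")
        if self.latency_min_ms >= self.latency_max_ms:
            raise ValueError("latency_min_ms must be < latency_max_ms")
        if self.consecutive_points < 1:
            raise ValueError("consecutive_points must be >= 1")
        if self.min_trials_per_condition < 0 or self.practice_trials < 0:
            raise ValueError("trial counts must be non-negative")
        if self.qc_eye_mode not in ("or", "and"):
            raise ValueError("qc_eye_mode must be 'or' or 'and'")
        if self.analysis_eye not in ("left", "right"):
            raise ValueError("analysis_eye must be 'left' or 'right'")
        if self.di_statistic not in ("mean_of_ratios", "ratio_of_means"):
            raise ValueError("unknown di_statistic")

    @property
    def sample_interval_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    def replace(self, **changes: Any) -> "StudyConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict[str, Any]) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        """Load a flat YAML mapping; unspecified fields keep their defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a flat mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_config(path: str | Path | None) -> StudyConfig:
    """Config from ``path``, or the defaults when ``path`` is None."""
    return StudyConfig() if path is None else StudyConfig.from_yaml(path)
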