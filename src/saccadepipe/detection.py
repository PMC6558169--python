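"""Saccade detection and acceptance gating.

A saccade-like event is a run of at least 2 consecutive samples whose
speed exceeds 50 deg/s. Its onset is where the direction-signed
acceleration leaves zero, searched within 50 ms before the velocity
peak (falling back to the minimum-|acceleration| sample when no zero is
found); its offset is where the direction-signed velocity first returns
to zero after the peak. An event is accepted as the trial's saccade when
its latency lies in [100, 600] ms, it lasts at least 12 ms, and a stable
fixation (within 1.5 deg of the cross, drifting < 0.6 deg) precedes it.
The earliest accepted event per eye is the primary saccade.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .config import StudyConfig
from .kinematics import KinematicTraces, differentiate_trace
from .records import EYES, TrialRecord

REJECTION_REASONS = ("latency_low", "latency_high", "too_short",
                     "no_fixation", "edge")


@dataclass
class SaccadeEvent:
    """One located saccade-like event of one eye."""

    eye: str
    onset_idx: int
    offset_idx: int
    peak_idx: int
    onset_ms: float
    offset_ms: float
    peak_time_ms: float
    peak_velocity_deg_s: float  # unsigned magnitude
    amplitude_deg: float  # |pos(offset) - pos(onset)|
    duration_ms: float
    direction: str  # movement direction from velocity sign at peak
    final_position_deg: float  # filtered position at offset
    edge: bool = False
    accepted: bool = False
    rejection_reasons: list = field(default_factory=list)


def candidate_events(velocity: np.ndarray,
                     config: StudyConfig | None = None) -> list[tuple[int, float]]:
    """(peak_index, signed peak velocity) per supra-threshold run.

    A run needs |v| > threshold at >= ``consecutive_points`` consecutive
    samples; each contiguous run yields one candidate anchored at its
    absolute-velocity maximum. NaN samples (outside the valid region)
    never participate.
    """
    config = config or StudyConfig()
    supra = np.abs(velocity) > config.velocity_threshold_deg_s
    supra &= ~np.isnan(velocity)
    if not supra.any():
        return []
    padded = np.concatenate(([False], supra, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    out = []
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start < config.consecutive_points:
            continue
        peak = start + int(np.argmax(np.abs(velocity[start:stop])))
        out.append((peak, float(velocity[peak])))
    return out


def locate_onset(acceleration: np.ndarray, velocity: np.ndarray, peak_idx: int,
                 config: StudyConfig | None = None,
                 valid_start: int = 0) -> tuple[int, bool]:
    """Onset index for the event peaking at ``peak_idx``; (index, edge flag).

    Within the 50 ms window before the velocity peak: starting from the
    direction-signed acceleration maximum (the signed acceleration crosses
    zero at the velocity peak itself, so the scan anchors on the rise),
    walk backward to the nearest sample where the signed acceleration has
    returned to zero and mark onset at the first accelerating sample after
    it. If the signed acceleration stays positive over the whole window,
    fall back to the minimum-|acceleration| sample. The edge flag is set
    when the search window is truncated by the valid region.
    """
    config = config or StudyConfig()
    span = int(round(config.onset_search_ms / config.sample_interval_ms))
    lo = peak_idx - span
    edge = lo < valid_start
    lo = max(lo, valid_start)
    sign = 1.0 if velocity[peak_idx] >= 0 else -1.0
    signed_acc = sign * acceleration[lo:peak_idx + 1]
    if signed_acc.size == 0:
        return peak_idx, True
    anchor = int(np.nanargmax(signed_acc))
    for k in range(anchor, -1, -1):
        if signed_acc[k] <= 0:
            return lo + min(k + 1, anchor), edge
    return lo + int(np.nanargmin(np.abs(signed_acc))), edge


def locate_offset(velocity: np.ndarray, peak_idx: int,
                  config: StudyConfig | None = None,
                  valid_stop: int | None = None) -> tuple[int, bool]:
    """First index after the peak where the direction-signed velocity
    drops to (or below) the offset threshold; (index, edge flag)."""
    config = config or StudyConfig()
    stop = velocity.size if valid_stop is None else valid_stop
    sign = 1.0 if velocity[peak_idx] >= 0 else -1.0
    for j in range(peak_idx + 1, stop):
        if sign * velocity[j] <= config.offset_velocity_threshold_deg_s:
            return j, False
    return stop - 1, True


def fixation_precedes(position: np.ndarray, onset_idx: int,
                      fixation_point: float = 0.0,
                      config: StudyConfig | None = None,
                      valid_start: int = 0) -> bool:
    """Stable pre-saccadic fixation on the cross.

    Over the pre-onset window (first valid sample up to onset), every
    sample must lie strictly within ``fixation_radius_deg`` of the
    fixation point and the position range (max - min) must stay strictly
    below ``fixation_drift_deg``. An empty window fails.
    """
    config = config or StudyConfig()
    window = position[valid_start:onset_idx]
    window = window[~np.isnan(window)]
    if window.size == 0:
        return False
    if np.max(np.abs(window - fixation_point)) >= config.fixation_radius_deg:
        return False
    return float(np.max(window) - np.min(window)) < config.fixation_drift_deg


def accept_saccade(event: SaccadeEvent, trial: TrialRecord,
                   traces: KinematicTraces,
                   config: StudyConfig | None = None) -> SaccadeEvent:
    """Apply the acceptance gates; failed gates land in rejection_reasons.

    Latency bounds are inclusive at both ends; the minimum duration is
    inclusive ("at least").
    """
    config = config or StudyConfig()
    reasons = []
    if event.onset_ms < config.latency_min_ms:
        reasons.append("latency_low")
    if event.onset_ms > config.latency_max_ms:
        reasons.append("latency_high")
    if event.duration_ms < config.min_duration_ms:
        reasons.append("too_short")
    if not fixation_precedes(traces.position_deg[event.eye], event.onset_idx,
                             0.0, config, traces.valid_start):
        reasons.append("no_fixation")
    if event.edge:
        reasons.append("edge")
    out = replace(event, rejection_reasons=reasons, accepted=not reasons)
    out.rejection_reasons = reasons
    return out


def _build_event(eye: str, peak_idx: int, peak_v: float,
                 traces: KinematicTraces, config: StudyConfig) -> SaccadeEvent:
    vel = traces.velocity_deg_s[eye]
    acc = traces.acceleration_deg_s2[eye]
    pos = traces.position_deg[eye]
    onset_idx, edge_on = locate_onset(acc, vel, peak_idx, config,
                                      traces.valid_start)
    offset_idx, edge_off = locate_offset(vel, peak_idx, config,
                                         traces.valid_stop)
    t = traces.t_ms
    return SaccadeEvent(
        eye=eye, onset_idx=onset_idx, offset_idx=offset_idx, peak_idx=peak_idx,
        onset_ms=float(t[onset_idx]), offset_ms=float(t[offset_idx]),
        peak_time_ms=float(t[peak_idx]),
        peak_velocity_deg_s=abs(peak_v),
        amplitude_deg=float(abs(pos[offset_idx] - pos[onset_idx])),
        duration_ms=float(t[offset_idx] - t[onset_idx]),
        direction="right" if peak_v >= 0 else "left",
        final_position_deg=float(pos[offset_idx]),
        edge=edge_on or edge_off,
    )


def detect_events(trial: TrialRecord, traces: KinematicTraces | None = None,
                  config: StudyConfig | None = None) -> dict[str, list[SaccadeEvent]]:
    """All located events per eye, acceptance gates applied."""
    config = config or StudyConfig()
    traces = traces or differentiate_trace(trial, config)
    out: dict[str, list[SaccadeEvent]] = {}
    for eye in EYES:
        events = []
        for peak_idx, peak_v in candidate_events(traces.velocity_deg_s[eye],
                                                 config):
            event = _build_event(eye, peak_idx, peak_v, traces, config)
            events.append(accept_saccade(event, trial, traces, config))
        out[eye] = events
    return out


def primary_saccade(trial: TrialRecord, traces: KinematicTraces | None = None,
                    config: StudyConfig | None = None
                    ) -> dict[str, SaccadeEvent | None]:
    """Earliest accepted event per eye (None when no event passes)."""
    events = detect_events(trial, traces, config)
    return {
        eye: min((e for e in events[eye] if e.accepted),
                 key=lambda e: e.onset_ms, default=None)
        for eye in EYES
    }


def events_table(trials: Sequence[TrialRecord],
                 config: StudyConfig | None = None) -> pd.DataFrame:
    """Tidy per-event table over a QC'ed cohort (all events, flags set)."""
    config = config or StudyConfig()
    rows = []
    for trial in trials:
        traces = differentiate_trace(trial, config)
        per_eye = detect_events(trial, traces, config)
        primaries = {
            eye: min((e for e in per_eye[eye] if e.accepted),
                     key=lambda e: e.onset_ms, default=None)
            for eye in EYES
        }
        for eye in EYES:
            for event in per_eye[eye]:
                subject_id, task, direction, eccentricity, trial_index = trial.key()
                rows.append({
                    "subject_id": subject_id, "group": trial.group,
                    "task": task, "direction": direction,
                    "eccentricity": eccentricity, "trial_index": trial_index,
                    "eye": eye,
                    "onset_ms": event.onset_ms, "offset_ms": event.offset_ms,
                    "peak_time_ms": event.peak_time_ms,
                    "peak_velocity_deg_s": event.peak_velocity_deg_s,
                    "amplitude_deg": event.amplitude_deg,
                    "duration_ms": event.duration_ms,
                    "saccade_direction": event.direction,
                    "final_position_deg": event.final_position_deg,
                    "accepted": event.accepted,
                    "primary": event is primaries[eye],
                    "rejection_reasons": ";".join(event.rejection_reasons),
                })
    columns = ["subject_id", "group", "task", "direction", "eccentricity",
               "trial_index", "eye", "onset_ms", "offset_ms", "peak_time_ms",
               "peak_velocity_deg_s", "amplitude_deg", "duration_ms",
               "saccade_direction", "final_position_deg", "accepted",
               "primary", "rejection_reasons"]
    return pd.DataFrame(rows, columns=columns)
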