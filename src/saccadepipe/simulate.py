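"""Synthetic binocular pro-/anti-saccade cohorts with ground truth.

The generator emulates the acquisition protocol of a step-saccade study:
1 s recordings at 300 Hz starting at the target jump, four conditions
(left/right x 9.2/18.4 deg) repeated 20 times per task, saccade latencies
drawn per task from a truncated normal, hypometric gains, a linear
amplitude-duration main sequence, tracker dropout bursts, anti-saccade
direction errors, and an injectable adduction slowing that reproduces the
binocular velocity dysconjugacy of internuclear ophthalmoparesis (INO).

Saccade waveforms are minimum-jerk polynomials: smooth, analytic, with
peak velocity exactly 1.875 * amplitude / duration, which makes every
trial's kinematics available as ground truth for the detector.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import ECCENTRICITY_DEG, TrialRecord, direction_sign

WINDOW_MS = 1000.0  # post-stimulus acquisition window

EYES_INDEX = {"left": 0, "right": 1}


@dataclass
class SimulationConfig:
    """Cohort-level generator settings.

    Latency centres (195/25 ms prosaccade, 305/45 ms anti-saccade),
    hypometric gain 0.93(5), and the 2.2 ms/deg + 21 ms main sequence are
    textbook-realistic values; anti-saccade direction-error probabilities
    default to 0.20 (HC) and 0.36 (MS). ``ino_assignments`` maps an MS
    subject index (0-based) to ``(adduction_factor, direction)`` with
    direction one of "left", "right", "both".
    """

    n_hc: int = 34
    n_ms: int = 33
    trials_per_condition: int = 20
    tasks: tuple[str, ...] = ("prosaccade", "antisaccade")
    sampling_rate_hz: float = 300.0
    latency_mean_ms: dict = field(
        default_factory=lambda: {"prosaccade": 195.0, "antisaccade": 305.0})
    latency_sd_ms: dict = field(
        default_factory=lambda: {"prosaccade": 25.0, "antisaccade": 45.0})
    #: Truncation keeps every true onset inside the 100-600 ms acceptance
    #: window with one-sample margin, so ground truth stays detectable.
    latency_bounds_ms: tuple[float, float] = (110.0, 590.0)
    main_sequence_slope_ms_per_deg: float = 2.2
    main_sequence_intercept_ms: float = 21.0
    gain_mean: float = 0.93
    gain_sd: float = 0.05
    noise_sd_deg: float = 0.1
    dropout_prob: float = 0.02
    dropout_burst_len: float = 3.0
    antisaccade_error_prob: dict = field(
        default_factory=lambda: {"HC": 0.20, "MS": 0.36})
    n_ino: int = 5
    ino_adduction_factor: float = 0.7
    ino_assignments: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hc < 0 or self.n_ms < 0:
            raise ValueError("group sizes must be non-negative")
        for p in (self.dropout_prob, *self.antisaccade_error_prob.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 < self.ino_adduction_factor <= 1.0:
            raise ValueError("ino_adduction_factor must lie in (0, 1]")
        for sd in (self.gain_sd, self.noise_sd_deg, *self.latency_sd_ms.values()):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")

    def resolved_ino_assignments(self) -> dict[int, tuple[float, str]]:
        """Explicit assignments, or the first n_ino MS subjects with the
        default factor, alternating affected direction left/right."""
        if self.ino_assignments is not None:
            return dict(self.ino_assignments)
        dirs = ["left", "right"]
        return {i: (self.ino_adduction_factor, dirs[i % 2])
                for i in range(min(self.n_ino, self.n_ms))}


@dataclass(frozen=True)
class TrialGroundTruth:
    """Per-eye noise-free kinematics of one simulated trial.

    Before noise, peak velocity is exactly 1.875 * amplitude / duration
    for the minimum-jerk waveform.
    """

    true_onset_ms: float
    true_duration_ms: dict  # eye -> ms
    true_amplitude_deg: float
    true_peak_velocity_deg_s: dict  # eye -> deg/s
    movement_direction: str
    correct_direction: bool


def minimum_jerk_position(amplitude: float, duration_ms: float, t_ms):
    """Minimum-jerk displacement at time t since movement onset.

    0 for t <= 0, ``amplitude`` for t >= duration, and
    A * (10 tau^3 - 15 tau^4 + 6 tau^5) with tau = t/duration in between.
    Peak velocity is 1.875 * A / D at tau = 0.5. Vectorised over t.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be strictly positive")
    tau = np.clip(np.asarray(t_ms, dtype=float) / duration_ms, 0.0, 1.0)
    return (amplitude * tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2))[()]


def minimum_jerk_peak_velocity(amplitude: float, duration_ms: float) -> float:
    """Analytic peak speed in deg/s (durations given in ms)."""
    return 1.875 * abs(amplitude) / (duration_ms / 1000.0)


def _draw_latency(task: str, cfg: SimulationConfig, rng: np.random.Generator) -> float:
    mean = cfg.latency_mean_ms[task]
    sd = cfg.latency_sd_ms[task]
    lo, hi = cfg.latency_bounds_ms
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _noise(noise_seed: int, sd: float, n: int, eye: str) -> tuple[np.ndarray, np.ndarray]:
    """Reproducible per-eye (x, y) measurement noise for one trial.

    Streams are independent between eyes (spawned from the trial's noise
    seed and the eye index) so binocular velocity ratios carry realistic
    trial-to-trial variability; regenerating an eye from the stored seed
    reproduces it bitwise.
    """
    nrng = np.random.default_rng([noise_seed, EYES_INDEX[eye]])
    if sd == 0:
        return np.zeros(n), np.zeros(n)
    return nrng.normal(0.0, sd, n), nrng.normal(0.0, sd, n)


def simulate_trial(
    task: str,
    direction: str,
    eccentricity: str,
    trial_index: int,
    subject_id: str,
    group: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[TrialRecord, TrialGroundTruth]:
    """One 300 Hz binocular trial over [0, 1000) ms.

    Latency is drawn from the task's truncated normal, amplitude is
    gain * |target|, duration follows the main sequence; anti-saccade
    trials move opposite the target unless a direction error is drawn.
    Both eyes receive the identical clean waveform (conjugate before any
    INO injection) plus independent per-eye additive Gaussian noise; the
    noise streams are reproducible from the stored trial seed, which lets
    apply_ino rebuild one eye bitwise.
    """
    n = int(round(WINDOW_MS / 1000.0 * cfg.sampling_rate_hz))
    t_ms = np.arange(n) * (1000.0 / cfg.sampling_rate_hz)

    latency = _draw_latency(task, cfg, rng)
    gain = max(0.2, float(rng.normal(cfg.gain_mean, cfg.gain_sd)))
    target = direction_sign(direction) * ECCENTRICITY_DEG[eccentricity]
    error = False
    if task == "antisaccade":
        error = bool(rng.random() < cfg.antisaccade_error_prob[group])
        move_sign = np.sign(target) if error else -np.sign(target)
    else:
        move_sign = np.sign(target)
    amplitude = gain * abs(target)
    duration = (cfg.main_sequence_slope_ms_per_deg * amplitude
                + cfg.main_sequence_intercept_ms)
    noise_seed = int(rng.integers(2**31))

    wave = move_sign * minimum_jerk_position(amplitude, duration, t_ms - latency)
    nxl, nyl = _noise(noise_seed, cfg.noise_sd_deg, n, "left")
    nxr, nyr = _noise(noise_seed, cfg.noise_sd_deg, n, "right")

    move_dir = "right" if move_sign > 0 else "left"
    truth = TrialGroundTruth(
        true_onset_ms=latency,
        true_duration_ms={"left": duration, "right": duration},
        true_amplitude_deg=amplitude,
        true_peak_velocity_deg_s={
            eye: minimum_jerk_peak_velocity(amplitude, duration)
            for eye in ("left", "right")},
        movement_direction=move_dir,
        correct_direction=not error,
    )
    trial = TrialRecord(
        subject_id=subject_id, group=group, task=task, direction=direction,
        eccentricity=eccentricity, trial_index=trial_index,
        t_ms=t_ms,
        x_left=wave + nxl, y_left=nyl, valid_left=np.zeros(n, dtype=int),
        x_right=wave + nxr, y_right=nyr, valid_right=np.zeros(n, dtype=int),
        extras={"sim": {
            "latency_ms": latency, "amplitude_deg": amplitude,
            "duration_ms": duration, "move_sign": float(move_sign),
            "noise_seed": noise_seed, "noise_sd_deg": cfg.noise_sd_deg,
        }, "truth": truth},
    )
    return trial, truth


def apply_ino(trial: TrialRecord, adduction_factor: float,
              direction: str) -> TrialRecord:
    """Slow the adducting eye of saccades moving in ``direction``.

    The adducting eye (left eye for rightward movements, right eye for
    leftward) keeps its amplitude but has its duration stretched by
    1/factor, so its true peak velocity becomes factor x the abducting
    eye's. Trials moving in the other direction are returned unchanged.
    Requires simulator provenance (the stored noise seed) so that
    factor = 1.0 reproduces the input bitwise.
    """
    if not 0.0 < adduction_factor <= 1.0:
        raise ValueError("adduction_factor must lie in (0, 1]")
    if "sim" not in trial.extras:
        raise ValueError("apply_ino needs a simulated trial with provenance")
    sim = trial.extras["sim"]
    truth: TrialGroundTruth = trial.extras["truth"]
    if direction not in ("left", "right"):
        raise ValueError(f"unknown direction {direction!r}")
    if truth.movement_direction != direction:
        return trial.copy()

    adducting = "left" if direction == "right" else "right"
    slow_duration = sim["duration_ms"] / adduction_factor
    wave = sim["move_sign"] * minimum_jerk_position(
        sim["amplitude_deg"], slow_duration, trial.t_ms - sim["latency_ms"])
    nx, _ = _noise(sim["noise_seed"], sim["noise_sd_deg"], trial.n_samples,
                   adducting)
    out = trial.copy()
    if adducting == "left":
        out.x_left = wave + nx
    else:
        out.x_right = wave + nx
    new_truth = dataclasses.replace(
        truth,
        true_duration_ms={**truth.true_duration_ms, adducting: slow_duration},
        true_peak_velocity_deg_s={
            **truth.true_peak_velocity_deg_s,
            adducting: minimum_jerk_peak_velocity(
                sim["amplitude_deg"], slow_duration)},
    )
    out.extras["truth"] = new_truth
    out.extras["sim"] = {**sim, "ino_factor": adduction_factor,
                         "ino_direction": direction}
    return out


def inject_missingness(trial: TrialRecord, dropout_prob: float,
                       burst_len: float, rng: np.random.Generator) -> TrialRecord:
    """Mark dropout bursts invalid (validity 4) on both eyes.

    Missing samples form a stationary two-state Markov chain whose
    stationary missing fraction equals ``dropout_prob`` exactly and whose
    mean burst length is ``burst_len`` samples.
    """
    if not 0.0 <= dropout_prob <= 1.0:
        raise ValueError("dropout_prob must lie in [0, 1]")
    out = trial.copy()
    n = trial.n_samples
    if dropout_prob == 0.0 or n == 0:
        return out
    if dropout_prob >= 1.0:
        out.valid_left[:] = 4
        out.valid_right[:] = 4
        return out
    burst_len = max(1.0, float(burst_len))
    p_leave = 1.0 / burst_len
    p_enter = dropout_prob * p_leave / (1.0 - dropout_prob)
    p_enter = min(1.0, p_enter)
    u = rng.random(n)
    missing = np.zeros(n, dtype=bool)
    state = bool(u[0] < dropout_prob)  # stationary start
    missing[0] = state
    for i in range(1, n):
        state = (u[i] >= p_leave) if state else (u[i] < p_enter)
        missing[i] = state
    out.valid_left[missing] = 4
    out.valid_right[missing] = 4
    return out


CONDITIONS = tuple(
    (direction, eccentricity)
    for direction in ("left", "right")
    for eccentricity in ("far", "close")
)


def simulate_cohort(cfg: SimulationConfig) -> tuple[list[TrialRecord], pd.DataFrame]:
    """Full cohort: per subject and task, 4 conditions x trials_per_condition.

    Deterministic given ``cfg.seed``. Returns the trials together with a
    tidy ground-truth table (one row per trial).
    """
    rng = np.random.default_rng(cfg.seed)
    ino = cfg.resolved_ino_assignments()
    trials: list[TrialRecord] = []
    rows = []
    subjects = ([("HC", f"HC{i + 1:03d}", None) for i in range(cfg.n_hc)]
                + [("MS", f"MS{i + 1:03d}", ino.get(i)) for i in range(cfg.n_ms)])
    for group, subject_id, ino_spec in subjects:
        for task in cfg.tasks:
            for direction, eccentricity in CONDITIONS:
                for trial_index in range(1, cfg.trials_per_condition + 1):
                    trial, truth = simulate_trial(
                        task, direction, eccentricity, trial_index,
                        subject_id, group, cfg, rng)
                    if ino_spec is not None and task == "prosaccade":
                        factor, affected = ino_spec
                        affected_dirs = (("left", "right") if affected == "both"
                                         else (affected,))
                        for adir in affected_dirs:
                            trial = apply_ino(trial, factor, adir)
                        truth = trial.extras["truth"]
                    trial = inject_missingness(
                        trial, cfg.dropout_prob, cfg.dropout_burst_len, rng)
                    trials.append(trial)
                    rows.append({
                        "subject_id": subject_id, "group": group, "task": task,
                        "direction": direction, "eccentricity": eccentricity,
                        "trial_index": trial_index,
                        "true_onset_ms": truth.true_onset_ms,
                        "true_amplitude_deg": truth.true_amplitude_deg,
                        "true_duration_left_ms": truth.true_duration_ms["left"],
                        "true_duration_right_ms": truth.true_duration_ms["right"],
                        "true_pv_left_deg_s": truth.true_peak_velocity_deg_s["left"],
                        "true_pv_right_deg_s": truth.true_peak_velocity_deg_s["right"],
                        "movement_direction": truth.movement_direction,
                        "correct_direction": truth.correct_direction,
                        "ino_affected": ino_spec is not None and task == "prosaccade"
                        and truth.movement_direction in (
                            ("left", "right") if ino_spec[1] == "both"
                            else (ino_spec[1],)),
                    })
    return trials, pd.DataFrame(rows)
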