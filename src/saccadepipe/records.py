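"""Domain types for binocular gaze trials.

A trial is a 1 s post-stimulus binocular recording sampled at a nominal
300 Hz: per-sample time (ms from target jump), per-eye horizontal and
vertical gaze position in degrees of visual angle (signed, rightward and
upward positive, 0 = screen centre), and a per-eye integer tracker
validity code in [0, 4], of which codes <= 1 mark usable samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Iterator, NamedTuple

import numpy as np

GROUPS = ("HC", "MS")
TASKS = ("prosaccade", "antisaccade")
DIRECTIONS = ("left", "right")
EYES = ("left", "right")

#: Target eccentricities in degrees of visual angle for the two step sizes.
ECCENTRICITY_DEG = {"close": 9.2, "far": 18.4}

#: Validity codes strictly above this value mark unusable samples.
VALID_CODE_MAX_USABLE = 1


class GazeFormatError(ValueError):
    """A gaze table violates the file contract (e.g. a missing column)."""


class GazeDataError(ValueError):
    """A gaze table parses but its content is inconsistent."""


class GazeSample(NamedTuple):
    """One binocular sample."""

    t_ms: float
    x_left: float
    y_left: float
    valid_left: int
    x_right: float
    y_right: float
    valid_right: int


def direction_sign(direction: str) -> int:
    """Signed horizontal axis convention: left < 0 < right."""
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    return -1 if direction == "left" else 1


@dataclass
class TrialRecord:
    """One trial's binocular sample sequence plus task/condition metadata.

    Sample channels are stored columnar as float/int arrays of equal
    length. ``extras`` carries opaque provenance (simulator ground truth,
    interpolation masks, unknown file columns) that round-trips where a
    serialisable representation exists but never influences analysis.
    """

    subject_id: str
    group: str
    task: str
    direction: str
    eccentricity: str
    trial_index: int
    t_ms: np.ndarray
    x_left: np.ndarray
    y_left: np.ndarray
    valid_left: np.ndarray
    x_right: np.ndarray
    y_right: np.ndarray
    valid_right: np.ndarray
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.eccentricity not in ECCENTRICITY_DEG:
            raise ValueError(f"unknown eccentricity {self.eccentricity!r}")
        direction_sign(self.direction)
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        for ch in ("x_left", "y_left", "x_right", "y_right"):
            setattr(self, ch, np.asarray(getattr(self, ch), dtype=float))
        for ch in ("valid_left", "valid_right"):
            codes = np.asarray(getattr(self, ch))
            if codes.size and (
                not np.issubdtype(codes.dtype, np.integer)
                and not np.all(codes == np.round(codes))
            ):
                raise GazeDataError(f"{self.key()}: non-integer validity codes")
            codes = codes.astype(int)
            if codes.size and (codes.min() < 0 or codes.max() > 4):
                raise GazeDataError(f"{self.key()}: validity codes outside [0, 4]")
            setattr(self, ch, codes)
        n = self.t_ms.size
        for ch in ("x_left", "y_left", "valid_left", "x_right", "y_right", "valid_right"):
            if getattr(self, ch).size != n:
                raise GazeDataError(f"{self.key()}: ragged sample channels")
        if n > 1 and np.any(np.diff(self.t_ms) <= 0):
            raise GazeDataError(f"{self.key()}: non-monotone sample times")

    # -- identity ---------------------------------------------------------

    def key(self) -> tuple[str, str, str, str, int]:
        return (self.subject_id, self.task, self.direction,
                self.eccentricity, self.trial_index)

    @property
    def target_deg(self) -> float:
        """Signed target position: sign follows direction, magnitude the step."""
        return direction_sign(self.direction) * ECCENTRICITY_DEG[self.eccentricity]

    @property
    def n_samples(self) -> int:
        return int(self.t_ms.size)

    # -- channel access ---------------------------------------------------

    def x(self, eye: str) -> np.ndarray:
        return self.x_left if eye == "left" else self.x_right

    def y(self, eye: str) -> np.ndarray:
        return self.y_left if eye == "left" else self.y_right

    def validity(self, eye: str) -> np.ndarray:
        return self.valid_left if eye == "left" else self.valid_right

    def samples(self) -> Iterator[GazeSample]:
        for i in range(self.n_samples):
            yield GazeSample(
                float(self.t_ms[i]),
                float(self.x_left[i]), float(self.y_left[i]), int(self.valid_left[i]),
                float(self.x_right[i]), float(self.y_right[i]), int(self.valid_right[i]),
            )

    def copy(self, **changes: Any) -> "TrialRecord":
        out = replace(self, **changes)
        if "extras" not in changes:
            out.extras = dict(self.extras)
        for ch in ("t_ms", "x_left", "y_left", "valid_left",
                   "x_right", "y_right", "valid_right"):
            if ch not in changes:
                setattr(out, ch, getattr(self, ch).copy())
        return out

    def equals(self, other: "TrialRecord") -> bool:
        """Field-by-field equality on metadata and every sample channel."""
        if self.key() != other.key() or self.group != other.group:
            return False
        return all(
            np.array_equal(getattr(self, ch), getattr(other, ch))
            for ch in ("t_ms", "x_left", "y_left", "valid_left",
                       "x_right", "y_right", "valid_right")
        )


def sort_key(trial: TrialRecord) -> tuple:
    return (trial.subject_id, trial.task, trial.direction,
            trial.eccentricity, trial.trial_index)
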