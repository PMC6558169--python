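"""Savitzky-Golay smoothing and differentiation of gaze traces.

Position, velocity, and acceleration are the 0th, 1st, and 2nd
derivatives of a sliding least-squares polynomial fit over an 11-point
window (36.7 ms at 300 Hz). The filter is zero-phase and reproduces
polynomials up to the fit order exactly; the first and last half-window
of samples have no full window and are flagged outside the valid region
(NaN) rather than padded with fabricated values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_coeffs, savgol_filter

from .config import StudyConfig
from .records import EYES, GazeDataError, TrialRecord


@dataclass
class KinematicTraces:
    """Per-eye position/velocity/acceleration on a shared time base.

    Values outside ``[valid_start, valid_stop)`` are NaN.
    """

    trial_key: tuple
    t_ms: np.ndarray
    position_deg: dict  # eye -> ndarray
    velocity_deg_s: dict
    acceleration_deg_s2: dict
    valid_start: int
    valid_stop: int

    @property
    def valid_slice(self) -> slice:
        return slice(self.valid_start, self.valid_stop)


def sg_kernel(window: int, polyorder: int, deriv_order: int, dt: float) -> np.ndarray:
    """Savitzky-Golay dot-product coefficients.

    The returned vector c satisfies: c . x[i-h : i+h+1] equals the
    deriv_order-th derivative at the window centre of the least-squares
    polynomial of degree ``polyorder`` fitted to those samples, with the
    sample spacing ``dt`` (so a first derivative comes out in units of
    x per unit of dt).
    """
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and > polyorder")
    if deriv_order not in (0, 1, 2):
        raise ValueError("deriv_order must be 0, 1, or 2")
    if dt <= 0:
        raise ValueError("dt must be strictly positive")
    return savgol_coeffs(window, polyorder, deriv=deriv_order, delta=dt,
                         use="dot")


def apply_kernel(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Slide a dot-product kernel over x; edges become NaN."""
    h = (kernel.size - 1) // 2
    out = np.full(x.size, np.nan)
    if x.size >= kernel.size:
        out[h:x.size - h] = np.convolve(x, kernel[::-1], mode="valid")
    return out


def differentiate_trace(trial: TrialRecord,
                        config: StudyConfig | None = None) -> KinematicTraces:
    """Position, velocity (deg/s), and acceleration (deg/s^2) per eye.

    The trial must already be gap-free (interpolated). Horizontal channel
    only; the half-window edges are NaN.
    """
    config = config or StudyConfig()
    n = trial.n_samples
    if n < config.sg_window:
        raise GazeDataError(
            f"{trial.key()}: {n} samples, shorter than the "
            f"{config.sg_window}-point filter window")
    dt_s = config.sample_interval_ms / 1000.0
    h = (config.sg_window - 1) // 2
    pos, vel, acc = {}, {}, {}
    for eye in EYES:
        x = trial.x(eye)
        series = []
        for deriv in (0, 1, 2):
            y = savgol_filter(x, config.sg_window, config.sg_polyorder,
                              deriv=deriv, delta=dt_s, mode="interp")
            y = y.astype(float)
            y[:h] = np.nan
            y[n - h:] = np.nan
            series.append(y)
        pos[eye], vel[eye], acc[eye] = series
    return KinematicTraces(
        trial_key=trial.key(), t_ms=trial.t_ms.copy(),
        position_deg=pos, velocity_deg_s=vel, acceleration_deg_s2=acc,
        valid_start=h, valid_stop=n - h,
    )
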