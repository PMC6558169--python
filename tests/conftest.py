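import numpy as np
import pytest

from saccadepipe.config import StudyConfig
from saccadepipe.records import TrialRecord
from saccadepipe.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def config():
    return StudyConfig()


def make_trial(
    x=None,
    n=300,
    valid_left=None,
    valid_right=None,
    x_left=None,
    x_right=None,
    subject_id="S01",
    group="HC",
    task="prosaccade",
    direction="right",
    eccentricity="far",
    trial_index=3,
    fs=300.0,
):
    """Hand-constructed trial with optional shared or per-eye x traces."""
    t = np.arange(n) * (1000.0 / fs)
    if x is None:
        x = np.zeros(n)
    xl = np.asarray(x_left if x_left is not None else x, dtype=float)
    xr = np.asarray(x_right if x_right is not None else x, dtype=float)
    vl = np.zeros(n, dtype=int) if valid_left is None else np.asarray(valid_left)
    vr = np.zeros(n, dtype=int) if valid_right is None else np.asarray(valid_right)
    return TrialRecord(
        subject_id=subject_id, group=group, task=task, direction=direction,
        eccentricity=eccentricity, trial_index=trial_index,
        t_ms=t, x_left=xl, y_left=np.zeros(n), valid_left=vl,
        x_right=xr, y_right=np.zeros(n), valid_right=vr,
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small noisy cohort reused by integration-level tests."""
    cfg = SimulationConfig(n_hc=3, n_ms=3, n_ino=1, trials_per_condition=6,
                           seed=42)
    return simulate_cohort(cfg)
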