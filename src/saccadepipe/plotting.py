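"""Diagnostic plots: per-trial traces with detected events, and the
cohort's DI Z-score strip plot with the screening cutoff."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .config import StudyConfig
from .detection import detect_events
from .kinematics import differentiate_trace
from .records import EYES, TrialRecord


def plot_trial(trial: TrialRecord, config: StudyConfig | None = None,
               axes=None):
    """Position and velocity traces of both eyes with event markers."""
    config = config or StudyConfig()
    traces = differentiate_trace(trial, config)
    events = detect_events(trial, traces, config)
    if axes is None:
        _, axes = plt.subplots(2, 1, sharex=True, figsize=(8, 6))
    colors = {"left": "tab:blue", "right": "tab:orange"}
    for eye in EYES:
        axes[0].plot(traces.t_ms, traces.position_deg[eye],
                     color=colors[eye], label=f"{eye} eye")
        axes[1].plot(traces.t_ms, traces.velocity_deg_s[eye],
                     color=colors[eye])
        for ev in events[eye]:
            style = "-" if ev.accepted else ":"
            for ax, series in ((axes[0], traces.position_deg[eye]),
                               (axes[1], traces.velocity_deg_s[eye])):
                ax.axvline(ev.onset_ms, color=colors[eye], ls=style, lw=0.8)
                ax.axvline(ev.offset_ms, color=colors[eye], ls=style, lw=0.8)
    axes[0].axhline(trial.target_deg, color="k", lw=0.6, ls="--",
                    label="target")
    axes[0].set_ylabel("position (deg)")
    axes[1].axhline(config.velocity_threshold_deg_s, color="k", lw=0.6,
                    ls="--")
    axes[1].axhline(-config.velocity_threshold_deg_s, color="k", lw=0.6,
                    ls="--")
    axes[1].set_ylabel("velocity (deg/s)")
    axes[1].set_xlabel("time (ms)")
    axes[0].legend(loc="best", fontsize=8)
    axes[0].set_title(" / ".join(map(str, trial.key())))
    return axes


def plot_di_z(ino: pd.DataFrame, ax=None):
    """Per-subject DI Z-scores by direction with the screening cutoff."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    rng = np.random.default_rng(0)  # jitter only
    for i, direction in enumerate(("left", "right")):
        block = ino[ino["direction"] == direction]
        for group, marker in (("HC", "o"), ("MS", "s")):
            rows = block[block["group"] == group]
            x = i + (0.12 if group == "MS" else -0.12)
            ax.scatter(x + rng.normal(0, 0.03, len(rows)), rows["Z_DI"],
                       marker=marker, s=18,
                       label=f"{group}" if i == 0 else None,
                       alpha=0.7)
        cut = block["cutoff"].dropna()
        if not cut.empty:
            ax.hlines(cut.iloc[0], i - 0.3, i + 0.3, color="red", lw=1.2)
        flagged = block[block["ino"]]
        for _, row in flagged.iterrows():
            ax.annotate(row["subject_id"], (i, row["Z_DI"]), fontsize=7)
    ax.set_xticks([0, 1], ["left", "right"])
    ax.set_ylabel("DI Z-score")
    ax.legend(loc="best", fontsize=8)
    return ax
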