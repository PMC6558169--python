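"""Dysconjugacy index and subclinical INO screening.

The dysconjugacy index (DI) is the ratio of the abducting to the
adducting eye's peak velocity in the large-amplitude (18.4 deg)
prosaccade condition, averaged over trials, computed separately for
leftward and rightward saccades (for a rightward saccade the right eye
abducts). Z-scores standardise each subject's DI against the healthy-
control distribution of the same direction:

    Z_DI = (DI - mean(DI_HC)) / SD(DI_HC)

and a subject screens positive for subclinical internuclear
ophthalmoparesis when Z exceeds the highest control Z plus a margin of 2
(strict inequality).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .config import StudyConfig

#: The "long" step size whose trials enter the DI.
DI_ECCENTRICITY = "far"


def dysconjugacy_index(subject_events: pd.DataFrame, direction: str,
                       config: StudyConfig | None = None) -> float:
    """DI of one subject in one movement direction.

    ``subject_events`` is a per-trial, per-eye metric table (adequate
    primary saccades). Only prosaccade far-condition trials whose primary
    saccade moved in ``direction`` with BOTH eyes accepted contribute;
    each trial yields PV(abducting)/PV(adducting) and the DI is their
    mean (or the ratio of mean velocities with
    config.di_statistic = "ratio_of_means"). NaN when no binocular trial
    exists (flagged undefined).
    """
    config = config or StudyConfig()
    if direction not in ("left", "right"):
        raise ValueError(f"unknown direction {direction!r}")
    rows = subject_events[
        (subject_events["task"] == "prosaccade")
        & (subject_events["eccentricity"] == DI_ECCENTRICITY)
        & (subject_events["adequate"])
        & (subject_events["saccade_direction"] == direction)
    ]
    abducting, adducting = (("right", "left") if direction == "right"
                            else ("left", "right"))
    pivot = rows.pivot_table(index=["direction", "trial_index"],
                             columns="eye", values="peak_velocity_deg_s")
    if ("left" not in pivot.columns or "right" not in pivot.columns
            or pivot.dropna().empty):
        return float("nan")
    both = pivot.dropna()
    if config.di_statistic == "ratio_of_means":
        return float(both[abducting].mean() / both[adducting].mean())
    return float((both[abducting] / both[adducting]).mean())


def di_table(metrics: pd.DataFrame,
             config: StudyConfig | None = None) -> pd.DataFrame:
    """DI per subject and direction over a cohort metric table."""
    config = config or StudyConfig()
    rows = []
    for (subject_id, group), grp in metrics.groupby(["subject_id", "group"],
                                                    sort=True):
        for direction in ("left", "right"):
            rows.append({
                "subject_id": subject_id, "group": group,
                "direction": direction,
                "DI": dysconjugacy_index(grp, direction, config),
            })
    return pd.DataFrame(rows, columns=["subject_id", "group", "direction", "DI"])


def z_scores(di_values, di_hc) -> np.ndarray:
    """Standardise DI values against the healthy-control distribution.

    Z = (DI - mean(DI_HC)) / SD(DI_HC) with the sample (ddof=1) SD.
    Requires at least two HC values with nonzero spread.
    """
    di_hc = np.asarray(di_hc, dtype=float)
    di_hc = di_hc[~np.isnan(di_hc)]
    if di_hc.size < 2:
        raise ValueError("need at least 2 healthy-control DI values")
    sd = float(np.std(di_hc, ddof=1))
    if sd == 0:
        raise ValueError("degenerate healthy-control DI distribution (SD = 0)")
    return (np.asarray(di_values, dtype=float) - di_hc.mean()) / sd


def ino_cutoff(hc_z_values, margin: float = 2.0) -> float:
    """Screening threshold: highest control Z plus the margin."""
    hc_z = np.asarray(hc_z_values, dtype=float)
    hc_z = hc_z[~np.isnan(hc_z)]
    if hc_z.size == 0:
        raise ValueError("no healthy-control Z values")
    return float(hc_z.max() + margin)


class DysconjugacyScreen(BaseEstimator):
    """Subclinical-INO screen over dysconjugacy indices.

    Fit on the healthy-control DI values of one direction; the fitted
    attributes are the HC mean and sample SD, the controls' own Z-scores,
    and the screening cutoff max(Z_HC) + margin. ``decision_function``
    returns Z-scores, ``predict`` the boolean screen (Z strictly above
    the cutoff).

    Parameters
    ----------
    margin : float, default 2.0
        Added to the highest control Z-score to form the cutoff.
    """

    def __init__(self, margin: float = 2.0):
        self.margin = margin

    def fit(self, X, y=None) -> "DysconjugacyScreen":
        X = np.asarray(X, dtype=float).ravel()
        X = X[~np.isnan(X)]
        if X.size < 2:
            raise ValueError("need at least 2 healthy-control DI values")
        self.mean_ = float(X.mean())
        self.sd_ = float(np.std(X, ddof=1))
        if self.sd_ == 0:
            raise ValueError("degenerate healthy-control DI distribution")
        self.hc_z_ = (X - self.mean_) / self.sd_
        self.cutoff_ = float(self.hc_z_.max() + self.margin)
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "cutoff_")
        return (np.asarray(X, dtype=float).ravel() - self.mean_) / self.sd_

    def predict(self, X) -> np.ndarray:
        return self.decision_function(X) > self.cutoff_


def screen_cohort(di: pd.DataFrame,
                  config: StudyConfig | None = None) -> pd.DataFrame:
    """Z-scores and INO labels for every subject and direction.

    The reference distribution is the HC subjects of the same direction
    (both directions pooled with config.ino_pooled); controls are scored
    against the full HC distribution including themselves unless
    config.di_leave_one_out is set.
    """
    config = config or StudyConfig()
    out = di.copy()
    out["Z_DI"] = np.nan
    out["cutoff"] = np.nan
    out["ino"] = False
    groups = [None] if config.ino_pooled else ["left", "right"]
    for direction in groups:
        sel = (slice(None) if direction is None
               else out["direction"] == direction)
        block = out[sel] if direction is not None else out
        hc = block[(block["group"] == "HC") & block["DI"].notna()]
        if len(hc) < 2:
            continue
        screen = DysconjugacyScreen(margin=config.ino_z_margin).fit(hc["DI"])
        idx = block.index[block["DI"].notna()]
        z = screen.decision_function(out.loc[idx, "DI"])
        if config.di_leave_one_out:
            # controls scored against the HC distribution excluding themselves
            for i in idx:
                if out.loc[i, "group"] == "HC":
                    others = hc.loc[hc.index != i, "DI"]
                    if len(others) >= 2 and np.std(others, ddof=1) > 0:
                        z[list(idx).index(i)] = float(
                            (out.loc[i, "DI"] - others.mean())
                            / np.std(others, ddof=1))
        out.loc[idx, "Z_DI"] = z
        out.loc[idx, "cutoff"] = screen.cutoff_
        out.loc[idx, "ino"] = z > screen.cutoff_
    return out
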