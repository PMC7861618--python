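"""Experiment-level tidy tables and the study's standard analyses.

Bridges the per-trial world (outcome codes, per-reach kinematics) and the
statistical models: build a tidy trial table, aggregate it per rat-session,
normalize each rat to its retraining baseline, and fit the per-group linear
mixed-effects models for laser and session effects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .session_metrics import (
    any_success_rate, first_success_rate, normalize_to_baseline,
)
from .stats import LmmFit, LmmSpec, fit_lmm
from .types import TRIAL_CODES

__all__ = [
    "trials_table", "session_summary", "normalized_success",
    "group_laser_lmm", "alternating_block_lmm",
]


def trials_table(sessions) -> pd.DataFrame:
    """Tidy per-trial table across synthetic sessions.

    Columns: rat, group, paw_side, stage, session (1-based, contiguous per
    rat), trial, outcome, laser, paw_through_slot, and the ground-truth
    kinematic summaries.
    """
    frames = []
    for s in sessions:
        t = s.trials.copy()
        t.insert(0, "rat", s.rat)
        t.insert(1, "group", s.group)
        t.insert(2, "paw_side", s.paw_side)
        t.insert(3, "stage", s.stage)
        t.insert(4, "session", s.session_index)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def session_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per rat-session aggregates of outcomes and kinematics.

    Success rates use the reach-trial denominator (codes 1,2,3,4,7),
    excluding paw-through-slot trials; kinematic means cover reach trials
    with finite values.  Sessions with no reach trials get NaN rates.
    """
    rows = []
    for (rat, group, stage, session), sub in trials.groupby(
            ["rat", "group", "stage", "session"], sort=False):
        usable = sub[~sub["paw_through_slot"].astype(bool)]
        codes = usable["outcome"].to_numpy(dtype=int)
        n_reach_trials = int(np.isin(codes, list(TRIAL_CODES)).sum())
        try:
            first = first_success_rate(codes)
            any_ = any_success_rate(codes)
        except ValueError:
            first = any_ = np.nan
        row = {
            "rat": rat, "group": group, "stage": stage, "session": session,
            "laser": int(stage == "laser_on"),
            "n_trials": n_reach_trials,
            "first_success": first, "any_success": any_,
        }
        for col in ("max_extent", "end_aperture", "end_orientation", "max_velocity"):
            v = usable[col].to_numpy(dtype=float)
            row[f"mean_{col}"] = float(np.nanmean(v)) if np.isfinite(v).any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def normalized_success(summary: pd.DataFrame,
                       value: str = "first_success") -> pd.DataFrame:
    """Add a per-rat baseline-normalized column ``{value}_norm``.

    The baseline is each rat's mean over its last two retraining sessions;
    rats with a zero or undefined baseline get NaN (analyzed on the raw
    scale instead).
    """
    out = summary.copy()
    out[f"{value}_norm"] = np.nan
    for rat, sub in summary.groupby("rat", sort=False):
        sub = sub.sort_values("session")
        try:
            norm = normalize_to_baseline(sub[value].to_numpy(),
                                         sub["stage"].to_numpy())
        except ValueError:
            continue
        out.loc[sub.index, f"{value}_norm"] = norm
    return out


def group_laser_lmm(summary: pd.DataFrame, response: str, group: str,
                    *, transform: str = "none",
                    re_formula: str = "1") -> LmmFit:
    """Per-group mixed model: response ~ laser * session, random rat terms.

    ``session`` is the global 1-based session index (retraining, laser-on,
    occlusion in order); ``laser`` indicates laser-on sessions.  The
    laser x session interaction captures progressive within-laser-phase
    change against the stable retraining/occlusion baseline.
    """
    data = summary[summary["group"] == group].copy()
    if data.empty:
        raise ValueError(f"no sessions for group {group!r}")
    spec = LmmSpec(response=response, fixed="laser * session",
                   groups="rat", re_formula=re_formula, transform=transform)
    return fit_lmm(data, spec)


def alternating_block_lmm(trials: pd.DataFrame, response: str = "max_extent",
                          block_length: int = 5,
                          re_formula: str = "1") -> LmmFit:
    """Mixed model for 5-off/5-on alternating-block sessions.

    Fits ``response ~ laser * trial_in_block`` on per-trial data with
    random rat effects.  A laser main effect without a laser x
    trial-within-block interaction is the signature of state-dependent
    (single-trial) switching rather than within-block drift.
    """
    data = trials.copy()
    data["trial_in_block"] = data["trial"].astype(int) % block_length
    data["laser"] = data["laser"].astype(int)
    data = data[np.isfinite(data[response].astype(float))]
    spec = LmmSpec(response=response, fixed="laser * trial_in_block",
                   groups="rat", re_formula=re_formula)
    return fit_lmm(data, spec)
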