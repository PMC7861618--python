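"""Session-, rat-, and group-level behavioral measures.

Outcome arithmetic follows the task's scoring scheme (see
:class:`~skilledreach.types.Outcome`): success rates count only true reach
trials (codes 1, 2, 3, 4, 7) in the denominator; first-reach success counts
code 1 and any-reach success codes 1 and 2.  Per-rat session series are
normalized to the mean of the last two retraining sessions; within-session
dynamics use trailing moving blocks of 10 trials with each rat's last value
carried forward so group averages are not distorted by dropout.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .types import (
    ANY_SUCCESS_CODES, FIRST_SUCCESS_CODES, TRIAL_CODES, AimsScore,
)

__all__ = [
    "first_success_rate", "any_success_rate", "normalize_to_baseline",
    "moving_block", "stratify_by_extent", "aims_scores",
]


def _success_rate(outcomes: Sequence[int], numerator: frozenset[int]) -> float:
    codes = np.asarray(outcomes, dtype=int)
    denom = int(np.isin(codes, list(TRIAL_CODES)).sum())
    if denom == 0:
        raise ValueError("no reach trials (codes 1,2,3,4,7) in the outcome list")
    return float(np.isin(codes, list(numerator)).sum() / denom)


def first_success_rate(outcomes: Sequence[int]) -> float:
    """Fraction of trials succeeding on the first reach.

    Number of scores of 1 divided by the number of reach trials (scores 1,
    2, 3, 4 and 7); non-trial codes (no pellet, tongue use, trigger errors,
    ...) are excluded from the denominator.
    """
    return _success_rate(outcomes, FIRST_SUCCESS_CODES)


def any_success_rate(outcomes: Sequence[int]) -> float:
    """Fraction of trials where the pellet was obtained on any reach (1 or 2)."""
    return _success_rate(outcomes, ANY_SUCCESS_CODES)


def normalize_to_baseline(values: Sequence[float],
                          stages: Sequence[str]) -> np.ndarray:
    """Divide a per-session series by the rat's baseline.

    The baseline is the mean of the last two sessions labeled
    ``'retraining'``.  A zero baseline leaves the ratio undefined (error);
    such series are analyzed on the raw scale via the asinh pathway.
    """
    vals = np.asarray(values, dtype=float)
    stages = np.asarray(stages)
    if vals.shape != stages.shape:
        raise ValueError("values and stage labels differ in length")
    retrain = np.flatnonzero(stages == "retraining")
    if len(retrain) < 2:
        raise ValueError("need at least two retraining sessions for a baseline")
    baseline = vals[retrain[-2:]].mean()
    if baseline == 0:
        raise ValueError("baseline is zero; normalized series undefined")
    return vals / baseline


def moving_block(values: Sequence[float], window: int = 10,
                 carry_to: int | None = None, kind: str = "mean") -> np.ndarray:
    """Trailing moving-block series over trials, with carry-forward.

    ``kind='success'`` computes the fraction of outcome scores equal to 1
    in each block; ``kind='mean'`` averages the values ignoring NaN.
    Blocks are trailing windows reported at the window's last trial, so the
    series starts at trial ``window``.  When ``carry_to`` exceeds the number
    of trials, the last block value is repeated (carried forward) so group
    averages over rats with different trial counts stay comparable.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if kind not in ("mean", "success"):
        raise ValueError("kind must be 'mean' or 'success'")
    vals = np.asarray(values, dtype=float)
    n = len(vals)
    if n == 0:
        return np.empty(0)
    out: list[float] = []
    for end in range(window, n + 1):
        block = vals[end - window:end]
        if kind == "success":
            out.append(float(np.mean(block == 1)))
        else:
            out.append(float(np.nanmean(block)) if np.isfinite(block).any() else np.nan)
    series = np.asarray(out)
    if carry_to is not None and carry_to > n and len(series):
        series = np.concatenate([series, np.full(carry_to - n, series[-1])])
    return series


def stratify_by_extent(trials: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Extent-matched stratification of trials into 1-mm bins from z = 0.

    ``trials`` needs columns ``max_extent`` (mm), ``outcome``, and
    optionally ``end_aperture`` / ``end_orientation``.  Within each bin
    [k, k+1) the success rate uses first successes (1) over first successes
    plus failures (4, 7); aperture and orientation are bin means over
    finite values.  Trials with maximum extent < 0 fall before the first
    bin; they are tallied and returned separately, not binned.
    """
    req = {"max_extent", "outcome"}
    if not req.issubset(trials.columns):
        raise ValueError(f"trials table needs columns {sorted(req)}")
    ext = trials["max_extent"].to_numpy(dtype=float)
    finite = np.isfinite(ext)
    negative = int(((ext < 0) & finite).sum())
    rows = []
    binnable = trials[finite & (ext >= 0)]
    if len(binnable):
        bins = np.floor(binnable["max_extent"].to_numpy(dtype=float)).astype(int)
        for k in range(int(bins.max()) + 1):
            sub = binnable[bins == k]
            out = sub["outcome"].to_numpy(dtype=int)
            n1 = int((out == 1).sum())
            nfail = int(np.isin(out, [4, 7]).sum())
            row = {
                "bin_lo": float(k), "bin_hi": float(k + 1), "n_trials": len(sub),
                "n_success": n1, "n_fail": nfail,
                "success_rate": n1 / (n1 + nfail) if (n1 + nfail) else np.nan,
            }
            for col in ("end_aperture", "end_orientation"):
                if col in sub.columns:
                    v = sub[col].to_numpy(dtype=float)
                    row[f"mean_{col.removeprefix('end_')}"] = (
                        float(np.nanmean(v)) if np.isfinite(v).any() else np.nan)
            rows.append(row)
    return pd.DataFrame(rows), negative


def aims_scores(score: AimsScore) -> dict[str, float]:
    """Composite abnormal-involuntary-movement scores.

    Severity (amplitude) and duration (basic) scores multiply into a
    composite per body region; the global score is the sum of the axial and
    limb composites; rotational bias is contralateral minus ipsilateral
    full rotations.
    """
    axial = score.axial_amplitude * score.axial_basic
    limb = score.limb_amplitude * score.limb_basic
    return {
        "axial_composite": axial,
        "limb_composite": limb,
        "global_score": axial + limb,
        "rotation_bias": score.contralateral_rotations - score.ipsilateral_rotations,
    }
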