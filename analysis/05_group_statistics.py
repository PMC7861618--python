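#!/usr/bin/env python
"""Group-level statistics on the simulated experiment.

Consumes the tables written by 01_simulate_experiment.py (regenerating
them if absent) and runs the study's statistical battery: per-group linear
mixed-effects models of session-mean maximum reach extent (laser, session,
and their interaction), baseline-normalized success rates with the asinh
transform, and the trialwise rank-sum comparison of within-session success
between the stim-during and control groups.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from skilledreach.session_metrics import moving_block
from skilledreach.stats import trialwise_ranksum
from skilledreach.summaries import (
    group_laser_lmm, normalized_success, session_summary, trials_table,
)
from skilledreach.synth import ExperimentDesign, generate_experiment

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def load_tables():
    t_path, s_path = OUT / "trials.csv", OUT / "session_summary.csv"
    if t_path.exists() and s_path.exists():
        return pd.read_csv(t_path), pd.read_csv(s_path)
    sessions = generate_experiment(ExperimentDesign(), seed=SEED)
    trials = trials_table(sessions)
    summary = normalized_success(session_summary(trials))
    return trials, summary


def main() -> None:
    OUT.mkdir(exist_ok=True)
    trials, summary = load_tables()

    coef_rows = []
    print("mixed models: mean max extent ~ laser * session, (1 | rat)")
    for group in summary["group"].unique():
        fit = group_laser_lmm(summary, "mean_max_extent", group)
        for term in fit.terms:
            r = fit[term]
            coef_rows.append({"group": group, "response": "mean_max_extent",
                              "term": term, **r})
        inter = fit["laser:session"]
        print(f"  {group:13s} laser x session: b = {inter['estimate']:+.3f}, "
              f"t({inter['df']:.0f}) = {inter['t']:.2f}, p = {inter['p']:.2e}")

        fit_s = group_laser_lmm(summary, "first_success_norm", group,
                                transform="asinh")
        for term in fit_s.terms:
            r = fit_s[term]
            coef_rows.append({"group": group,
                              "response": "asinh_first_success_norm",
                              "term": term, **r})
    pd.DataFrame(coef_rows).to_csv(OUT / "lmm_coefficients.csv", index=False)

    # within-session success dynamics: stim-during vs control on the last
    # laser session, moving block of 10 trials with carry-forward
    last_laser = trials[(trials.stage == "laser_on")
                        & (trials.session == trials[trials.stage == "laser_on"]
                           .session.max())]
    series = {}
    for group in ("stim_during", "control"):
        per_rat = []
        sub = last_laser[last_laser.group == group]
        carry = int(sub.groupby("rat").size().max())
        for _, rat_trials in sub.groupby("rat"):
            per_rat.append(moving_block(rat_trials.outcome.to_numpy(),
                                        window=10, carry_to=carry,
                                        kind="success"))
        width = max(len(s) for s in per_rat)
        series[group] = np.vstack([
            np.pad(s, (0, width - len(s)), constant_values=s[-1])
            for s in per_rat])
    mask, pvals = trialwise_ranksum(series["stim_during"], series["control"],
                                    alpha=0.01)
    pd.DataFrame({"trial": np.arange(len(mask)) + 10,
                  "p": pvals, "significant": mask}
                 ).to_csv(OUT / "trialwise_ranksum_last_laser.csv", index=False)
    print(f"\ntrialwise rank-sum (last laser session, stim_during vs control): "
          f"{int(mask.sum())}/{len(mask)} trials significant at p < 0.01")


if __name__ == "__main__":
    main()
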