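#!/usr/bin/env python
"""Simulate the default optogenetic reaching experiment and tabulate it.

Generates the standard design — stim-during, stim-between and control
groups, 6 rats each, 22 sessions (2 retraining, 10 laser-on, 10 occlusion)
of 60 trials — and writes the tidy per-trial table and per-session summary
that every later analysis consumes.
"""

from pathlib import Path

from skilledreach.summaries import normalized_success, session_summary, trials_table
from skilledreach.synth import ExperimentDesign, generate_experiment

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    sessions = generate_experiment(ExperimentDesign(), seed=SEED)
    trials = trials_table(sessions)
    summary = normalized_success(session_summary(trials))

    trials.to_csv(OUT / "trials.csv", index=False)
    summary.to_csv(OUT / "session_summary.csv", index=False)

    n_rats = trials["rat"].nunique()
    print(f"simulated {n_rats} rats, {len(sessions)} sessions, "
          f"{len(trials)} trials (seed {SEED})")
    base = summary[summary.stage == "retraining"]
    late = summary[(summary.stage == "laser_on") & (summary.session >= 10)]
    for group, sub in summary.groupby("group"):
        b = sub[sub.stage == "retraining"]["first_success"].mean()
        l = sub[(sub.stage == "laser_on") & (sub.session >= 10)]["first_success"].mean()
        print(f"  {group:13s} first-success: retraining {b:.2f} -> "
              f"late laser {l:.2f}")


if __name__ == "__main__":
    main()
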