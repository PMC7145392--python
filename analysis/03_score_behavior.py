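"""Score interference-task logs into weighted RTs and wRTI indices.

Reads the trial table (subject_id, session, task, condition, rt, correct),
removes RTs outside 30-3000 ms, computes wRT = mean RT / proportion correct
per condition, and the interference index wRTI (incongruent - congruent for
the Flanker; block 3 - block 1 for the Stroop).
"""

import argparse
from pathlib import Path

import pandas as pd

from headnet.behavior import compute_wrti, filter_trials, score_conditions

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--trials", type=Path, default=Path("results/trials.csv"))
parser.add_argument("--out", type=Path, default=Path("results/wrti.csv"))
args = parser.parse_args()

trials = pd.read_csv(args.trials)
conditions = score_conditions(filter_trials(trials))
wrti = compute_wrti(conditions)
args.out.parent.mkdir(parents=True, exist_ok=True)
conditions.to_csv(args.out.with_name("condition_scores.csv"), index=False)
wrti.to_csv(args.out, index=False)

group = wrti.groupby(["session", "task"])["wrti"].agg(["mean", "std"]).round(2)
print("group wRTI (mean, sd):")
print(group)
print(f"written to {args.out}")
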