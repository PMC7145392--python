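"""Scoring of Flanker (FIT) and Stroop (SCWIT) interference-task logs.

Both tasks are scored with a weighted reaction time that inflates mean RT by
inverse accuracy, ``wRT = mean_RT * (1/ACC%) * 100`` with accuracy in
percent — i.e. mean RT divided by the proportion of correct responses — so a
subject cannot trade accuracy for speed.  The interference index wRTI is the
wRT difference between the high- and low-interference conditions
(incongruent − congruent for the Flanker; block 3 − block 1 for the Stroop;
block 2 is scored but does not enter the index).  Higher wRTI means more
interference, i.e. worse inhibitory control.

Trials with RT < 30 ms or > 3000 ms are removed before scoring (strictly
outside; boundary values are retained), and accuracy is computed on the
retained trials.
"""

from __future__ import annotations

import pandas as pd

RT_MIN_MS = 30.0
RT_MAX_MS = 3000.0

#: (high-interference, low-interference) condition labels per task.
WRTI_CONTRASTS = {
    "FIT": ("incongruent", "congruent"),
    "SCWIT": ("block3", "block1"),
}

__all__ = [
    "RT_MIN_MS",
    "RT_MAX_MS",
    "WRTI_CONTRASTS",
    "filter_trials",
    "weighted_rt",
    "score_conditions",
    "compute_wrti",
    "score_trials",
]


def filter_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Drop trials with RT strictly below 30 ms or strictly above 3000 ms."""
    mask = (trials["rt"] >= RT_MIN_MS) & (trials["rt"] <= RT_MAX_MS)
    return trials.loc[mask].copy()


def weighted_rt(mean_rt: float, acc_percent: float) -> float:
    """wRT = mean_rt * (1 / acc_percent) * 100 = mean_rt / proportion correct.

    Raises ``ValueError`` for zero accuracy (the weighting is undefined).
    """
    if acc_percent <= 0:
        raise ValueError("wRT undefined at zero accuracy")
    return mean_rt * (1.0 / acc_percent) * 100.0


def score_conditions(trials: pd.DataFrame) -> pd.DataFrame:
    """Per subject/session/task/condition accuracy, mean RT and wRT.

    Input rows are single (already filtered) trials with columns
    ``subject_id, session, task, condition, rt, correct``.  Accuracy is
    percent correct among retained trials; conditions with no retained
    trials raise.
    """
    if len(trials) == 0:
        raise ValueError("no trials to score")
    keys = ["subject_id", "session", "task", "condition"]
    grouped = trials.groupby(keys, sort=True)
    out = grouped.agg(
        n_trials=("rt", "size"),
        mean_rt=("rt", "mean"),
        acc=("correct", lambda c: 100.0 * c.mean()),
    ).reset_index()
    out["wrt"] = [weighted_rt(m, a) for m, a in zip(out["mean_rt"], out["acc"])]
    return out


def compute_wrti(scores: pd.DataFrame) -> pd.DataFrame:
    """Interference index per subject/session/task from condition scores.

    wRTI = wRT(high-interference) − wRT(low-interference), with the
    condition pair taken from :data:`WRTI_CONTRASTS`.  A missing condition
    raises.
    """
    rows = []
    for (subject, session, task), grp in scores.groupby(
        ["subject_id", "session", "task"], sort=True
    ):
        try:
            high, low = WRTI_CONTRASTS[task]
        except KeyError:
            raise ValueError(f"unknown task {task!r}") from None
        wrt = grp.set_index("condition")["wrt"]
        if high not in wrt.index or low not in wrt.index:
            raise ValueError(
                f"missing condition for {subject}/{session}/{task}: "
                f"need {high!r} and {low!r}"
            )
        rows.append(
            {
                "subject_id": subject,
                "session": session,
                "task": task,
                "wrti": wrt[high] - wrt[low],
            }
        )
    return pd.DataFrame(rows)


def score_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Filter raw trials and return the per-subject wRTI table."""
    return compute_wrti(score_conditions(filter_trials(trials)))
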