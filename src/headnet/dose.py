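"""Dose-response tests: exposure vs pre→post change in EEG summaries.

The primary hypothesis is a linear dose relationship between cumulative
head-impact exposure (wCHI, or the count-only nHI variant) and the
post-minus-pre change in each EEG summary (band-averaged dWPLI/COH/SPD and
graph metrics).  Each metric × band is tested with a Pearson correlation
(two-sided p from the t distribution with n−2 df), Bonferroni-corrected
across the five frequency bands (p × 5, capped at 1), with a 500-draw
percentile bootstrap CI over subject resampling for effect-size context.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

N_BANDS_BONFERRONI = 5

__all__ = ["delta_metrics", "pearson_with_bootstrap", "correlate_exposure"]


def delta_metrics(pre: pd.DataFrame, post: pd.DataFrame) -> pd.DataFrame:
    """Post − pre per subject for every metric column.

    Both frames are indexed by subject (or carry a ``subject_id`` column);
    subjects must match one-to-one across sessions.
    """
    if "subject_id" in pre.columns:
        pre = pre.set_index("subject_id")
    if "subject_id" in post.columns:
        post = post.set_index("subject_id")
    if set(pre.index) != set(post.index):
        raise ValueError("subjects do not match across sessions")
    post = post.reindex(pre.index)
    return post - pre


def pearson_with_bootstrap(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 500,
    seed: int | np.random.SeedSequence = 0,
) -> dict:
    """Pearson r, two-sided p, and a percentile bootstrap 95% CI.

    Subject pairs are resampled with replacement ``n_boot`` times;
    degenerate resamples (zero variance in either variable) are redrawn.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in correlation input")
    r, p = stats.pearsonr(x, y)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if np.std(x[idx]) > 0 and np.std(y[idx]) > 0:
                break
        boots[b] = stats.pearsonr(x[idx], y[idx])[0]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {"r": float(r), "p_raw": float(p), "ci_low": float(lo), "ci_high": float(hi), "n": n}


def correlate_exposure(
    deltas: pd.DataFrame,
    exposure: pd.Series,
    n_boot: int = 500,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Dose-response table: one row per metric column of ``deltas``.

    ``deltas`` columns are (metric, band) tuples or ``"metric:band"``
    strings; rows are subjects aligned with ``exposure`` (wCHI, or nHI for
    the count-only sensitivity variant).  The Bonferroni factor is the five
    frequency bands.
    """
    exposure = exposure.reindex(deltas.index)
    if exposure.isna().any():
        raise ValueError("exposure missing for some subjects")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(deltas.shape[1])
    rows = []
    for col, sub_seed in zip(deltas.columns, seeds):
        if isinstance(col, tuple):
            metric, band = col
        else:
            metric, _, band = str(col).partition(":")
        res = pearson_with_bootstrap(exposure.to_numpy(), deltas[col].to_numpy(), n_boot, sub_seed)
        res["p_bonferroni"] = min(1.0, res["p_raw"] * N_BANDS_BONFERRONI)
        rows.append({"metric": metric, "band": band, **res})
    return pd.DataFrame(rows)
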