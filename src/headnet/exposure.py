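"""Weighted cumulative head-impact exposure (wCHI) from impact kinematics.

Head-worn inertial sensors report three peak kinematic measures per
accelerative event: peak linear acceleration (PLA, g), peak rotational
velocity (PRV, rad/s) and peak rotational acceleration (PRA, krad/s^2).
The three are strongly interdependent, so per-impact severity is summarized
by a principal-component composite: the kinematics of all confirmed impacts
are pooled and z-transformed, the 3x3 covariance of the z-data (i.e. the
correlation matrix of the raw data) is eigendecomposed, and each impact's
principal component score (PCS) is the sum of its projections onto the
eigenvectors weighted by the fraction of variance each explains.  An
athlete's wCHI is the sum of their PCS values over the season; nHI is the
plain count of confirmed impacts (a magnitude-free sensitivity variant).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

KINEMATIC_COLUMNS = ["pla", "prv", "pra"]

#: Sensors ship a built-in trigger filter: only events with PLA above this
#: value (in g) are recorded, strictly.
PLA_THRESHOLD_G = 16.0

__all__ = [
    "KINEMATIC_COLUMNS",
    "PLA_THRESHOLD_G",
    "filter_impacts",
    "principal_component_scores",
    "compute_wchi",
]


def filter_impacts(records: pd.DataFrame, pla_threshold: float = PLA_THRESHOLD_G) -> pd.DataFrame:
    """Keep confirmed impacts with PLA strictly above the trigger threshold.

    Parameters
    ----------
    records : DataFrame
        One row per accelerative event with columns ``athlete_id``, ``pla``,
        ``prv``, ``pra`` and boolean ``confirmed`` (video-consensus flag;
        events not confirmed are false positives and excluded).
    pla_threshold : float
        Trigger threshold in g. Rows with ``pla == pla_threshold`` are
        excluded (the sensor records only strictly larger events).
    """
    mask = records["confirmed"].astype(bool) & (records["pla"] > pla_threshold)
    return records.loc[mask].copy()


def principal_component_scores(confirmed: pd.DataFrame) -> np.ndarray:
    """Per-impact principal component scores (PCS) from pooled z-kinematics.

    All confirmed impacts are pooled across athletes; each kinematic column
    is z-transformed (mean 0, sd 1, ddof=1); the covariance of the z-data is
    eigendecomposed; and PCS_i = sum_k (lambda_k / sum lambda) * score_ik
    where score_ik is impact i's projection on eigenvector k.  Eigenvector
    signs are fixed so the PLA loading is non-negative (larger = more
    severe).

    Raises
    ------
    ValueError
        If fewer than two confirmed impacts are available or a kinematic
        column has zero variance (degenerate pooled sample).
    """
    if len(confirmed) < 2:
        raise ValueError("PCS requires at least 2 confirmed impacts")
    x = confirmed[KINEMATIC_COLUMNS].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [c for c, s in zip(KINEMATIC_COLUMNS, sd) if s == 0]
        raise ValueError(f"zero-variance kinematic column(s): {bad}")
    z = (x - x.mean(axis=0)) / sd
    cov = np.cov(z, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    # eigh returns ascending order; sign fixed by non-negative PLA loading
    flip = np.sign(eigvecs[0, :])
    flip[flip == 0] = 1.0
    eigvecs = eigvecs * flip
    scores = z @ eigvecs
    weights = eigvals / eigvals.sum()
    return scores @ weights


def compute_wchi(
    confirmed: pd.DataFrame,
    roster: list | None = None,
) -> pd.DataFrame:
    """Per-athlete exposure summary: wCHI (sum of PCS) and nHI (count).

    Parameters
    ----------
    confirmed : DataFrame
        Confirmed impacts (output of :func:`filter_impacts`).
    roster : list, optional
        Athlete ids to report. Athletes on the roster with no confirmed
        impacts get ``wchi = 0`` and ``nhi = 0`` (low/zero-exposure athletes
        stay in the dose-response analysis).

    Returns
    -------
    DataFrame indexed by ``athlete_id`` with columns ``wchi`` and ``nhi``.
    """
    pcs = principal_component_scores(confirmed)
    per_impact = confirmed.assign(pcs=pcs)
    summary = per_impact.groupby("athlete_id")["pcs"].agg(wchi="sum", nhi="count")
    if roster is not None:
        summary = summary.reindex(roster, fill_value=0.0)
    summary["nhi"] = summary["nhi"].astype(int)
    summary.index.name = "athlete_id"
    return summary
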