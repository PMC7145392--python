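"""Behavioral partial-least-squares correlation of brain features and
interference scores.

The brain matrix stacks, per subject × session observation (rows,
subject-major then pre/post), three column blocks: dWPLI pair × frequency,
COH pair × frequency and SPD channel × frequency (at the study design of 28
channels and 99 bins: 37422 + 37422 + 2772 = 77616 columns over 36 rows).
The behavior matrix holds the two interference scores (SCWIT wRTI, FIT
wRTI) on the same rows.

Within each condition (pre, post) every behavior column is Pearson-
correlated with every brain column across subjects and the condition-wise
rows are stacked into R (4 × p).  The SVD R = U S Vᵀ yields four latent
variables (LVs): behavior saliences U, brain saliences V, and squared
singular values as fractions of covariance explained.  Significance of each
LV comes from a permutation test (subject assignment of behavior rows
shuffled within condition; p = fraction of permuted singular values at or
above the observed).  Salience reliability comes from bootstrap resampling
of subjects (both sessions move together) with Procrustes alignment of each
resample's saliences to the original solution; bootstrap ratio = mean
bootstrapped salience / bootstrap SE, with |ratio| > 1.96 flagged reliable.
Scalp scores project each observation's brain row onto a brain salience;
their pre→post change is tested against exposure with the dose-response
machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from headnet.dose import pearson_with_bootstrap
from headnet.spectral import BANDS

__all__ = [
    "PLSModel",
    "assemble_brain_matrix",
    "stacked_correlation",
    "svd_pls",
    "permutation_test",
    "bootstrap_saliences",
    "scalp_scores",
    "delta_scalp_vs_exposure",
    "band_bootstrap_summary",
    "run_behavioral_pls",
]

SESSIONS = ("pre", "post")
BEHAVIOR_COLUMNS = ("SCWIT", "FIT")
BOOTSTRAP_RATIO_THRESHOLD = 1.96


@dataclass
class PLSModel:
    """Core results of a behavioral PLS run."""

    R: np.ndarray
    behavior_saliences: np.ndarray  # U: (4, 4)
    singular_values: np.ndarray  # (4,)
    brain_saliences: np.ndarray  # V: (p, 4)
    covariance_explained: np.ndarray  # s^2 / sum s^2
    perm_p: np.ndarray | None = None
    bootstrap_ratios: np.ndarray | None = None  # (p, 4)
    scalp_scores: np.ndarray | None = field(default=None)  # (n_obs, 4)


def assemble_brain_matrix(
    dwpli: dict,
    coh: dict,
    spd: dict,
    subjects: list,
    pairs: list[tuple[str, str]],
    channels: list[str],
    freqs: np.ndarray,
) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Stack per-observation connectivity and SPD into the brain matrix.

    ``dwpli``/``coh`` map (subject, session) to pair × frequency arrays and
    ``spd`` to channel × frequency arrays.  Rows are subject-major then
    session (pre, post); columns are the dWPLI block, then COH, then SPD,
    each pair-/channel-major then frequency.  Returns the matrix plus row
    and column descriptor frames.
    """
    n_freq = len(freqs)
    rows, row_info = [], []
    for subject in subjects:
        for session in SESSIONS:
            key = (subject, session)
            if key not in dwpli or key not in coh or key not in spd:
                raise ValueError(f"missing session data for {key}")
            row = np.concatenate(
                [dwpli[key].ravel(), coh[key].ravel(), spd[key].ravel()]
            )
            rows.append(row)
            row_info.append({"subject_id": subject, "session": session})
    brain = np.vstack(rows)
    col_info = pd.DataFrame(
        {
            "block": (
                ["dwpli"] * (len(pairs) * n_freq)
                + ["coh"] * (len(pairs) * n_freq)
                + ["spd"] * (len(channels) * n_freq)
            ),
            "freq": np.concatenate(
                [np.tile(freqs, len(pairs)), np.tile(freqs, len(pairs)), np.tile(freqs, len(channels))]
            ),
        }
    )
    expected = 2 * len(pairs) * n_freq + len(channels) * n_freq
    if brain.shape[1] != expected:
        raise ValueError("block sizes inconsistent with pairs/channels/freqs")
    return brain, pd.DataFrame(row_info), col_info


def _condition_correlations(brain: np.ndarray, behavior: np.ndarray) -> np.ndarray:
    """Pearson correlations of each behavior column with each brain column."""
    bx = brain - brain.mean(axis=0)
    by = behavior - behavior.mean(axis=0)
    sx = np.sqrt((bx**2).sum(axis=0))
    sy = np.sqrt((by**2).sum(axis=0))
    zero = sx == 0
    if zero.any():
        warnings.warn(f"{zero.sum()} zero-variance brain columns set to r=0", stacklevel=2)
    if np.any(sy == 0):
        raise ValueError("zero-variance behavior column")
    num = by.T @ bx  # (n_behaviors, p)
    denom = np.outer(sy, np.where(zero, 1.0, sx))
    r = num / denom
    r[:, zero] = 0.0
    return r


def stacked_correlation(
    brain: np.ndarray, behavior: np.ndarray, conditions: np.ndarray
) -> np.ndarray:
    """Condition-wise stacked brain-behavior correlation matrix R (4 × p).

    Row order is condition-major over (pre, post) then behavior column
    order, i.e. (pre, SCWIT), (pre, FIT), (post, SCWIT), (post, FIT) for the
    default behavior layout.
    """
    conditions = np.asarray(conditions)
    blocks = []
    for cond in SESSIONS:
        sel = conditions == cond
        if sel.sum() < 3:
            raise ValueError(f"condition {cond!r} has fewer than 3 observations")
        blocks.append(_condition_correlations(brain[sel], behavior[sel]))
    return np.vstack(blocks)


def svd_pls(R: np.ndarray) -> PLSModel:
    """SVD of the stacked correlation matrix: R = U S Vᵀ."""
    if not np.all(np.isfinite(R)):
        raise ValueError("R contains non-finite values")
    u, s, vt = np.linalg.svd(R, full_matrices=False)
    # SVD signs are arbitrary; fix each LV so its dominant behavior-salience
    # entry is positive, making scalp-score directions reproducible
    for k in range(u.shape[1]):
        if u[np.argmax(np.abs(u[:, k])), k] < 0:
            u[:, k] = -u[:, k]
            vt[k, :] = -vt[k, :]
    return PLSModel(
        R=R,
        behavior_saliences=u,
        singular_values=s,
        brain_saliences=vt.T,
        covariance_explained=s**2 / np.sum(s**2),
    )


def contrast_pls(R: np.ndarray, contrasts: np.ndarray) -> PLSModel:
    """Non-rotated PLS: project R onto supplied orthogonal contrast weights.

    Instead of letting the SVD rotate to the optimal behavior weights, each
    contrast column c (over the 4 condition × behavior rows) defines an LV
    directly: brain salience ∝ Rᵀ c with "singular value" ‖Rᵀ c‖.  Used when
    a specific hypothesis (e.g. post-season increase in both interference
    scores) should be tested as stated rather than discovered.
    """
    c = np.asarray(contrasts, dtype=float)
    if c.ndim != 2 or c.shape[0] != R.shape[0]:
        raise ValueError("contrasts must be (n_rows_of_R, n_contrasts)")
    c = c / np.linalg.norm(c, axis=0)
    proj = R.T @ c  # (p, k)
    s = np.linalg.norm(proj, axis=0)
    v = np.divide(proj, s, out=np.zeros_like(proj), where=s > 0)
    return PLSModel(
        R=R,
        behavior_saliences=c,
        singular_values=s,
        brain_saliences=v,
        covariance_explained=s**2 / np.sum(s**2),
    )


def _shuffle_within_condition(
    behavior: np.ndarray, conditions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    out = behavior.copy()
    for cond in SESSIONS:
        idx = np.flatnonzero(conditions == cond)
        out[idx] = behavior[rng.permutation(idx)]
    return out


def permutation_test(
    brain: np.ndarray,
    behavior: np.ndarray,
    conditions: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Permutation p per LV: fraction of permutations whose i-th singular
    value is at least the observed i-th singular value."""
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    s_obs = np.linalg.svd(
        stacked_correlation(brain, behavior, conditions), compute_uv=False
    )
    count = np.zeros_like(s_obs)
    for _ in range(n_perm):
        perm = _shuffle_within_condition(behavior, conditions, rng)
        s_perm = np.linalg.svd(
            stacked_correlation(brain, perm, conditions), compute_uv=False
        )
        count += s_perm >= s_obs
    return count / n_perm


def _procrustes_rotation(u_boot: np.ndarray, u_orig: np.ndarray) -> np.ndarray:
    a, _, bt = np.linalg.svd(u_boot.T @ u_orig)
    return a @ bt


def bootstrap_saliences(
    brain: np.ndarray,
    behavior: np.ndarray,
    conditions: np.ndarray,
    subject_ids: np.ndarray,
    n_boot: int = 500,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Bootstrap ratios of the brain saliences, (p, n_LV).

    Subjects are resampled with replacement (all of a subject's rows move
    together); each resample's saliences are Procrustes-aligned to the
    original solution; ratio = mean aligned salience / bootstrap SE.
    Resamples with two or fewer unique subjects are redrawn.
    """
    if n_boot < 100:
        raise ValueError("need at least 100 bootstraps")
    rng = np.random.default_rng(seed)
    subject_ids = np.asarray(subject_ids)
    unique_subjects = pd.unique(subject_ids)
    n_subjects = len(unique_subjects)
    row_of = {s: np.flatnonzero(subject_ids == s) for s in unique_subjects}
    orig = svd_pls(stacked_correlation(brain, behavior, conditions))
    boots = np.empty((n_boot,) + orig.brain_saliences.shape)
    for b in range(n_boot):
        while True:
            draw = unique_subjects[rng.integers(0, n_subjects, size=n_subjects)]
            if len(set(draw)) > 2:
                break
        idx = np.concatenate([row_of[s] for s in draw])
        model = svd_pls(stacked_correlation(brain[idx], behavior[idx], conditions[idx]))
        q = _procrustes_rotation(model.behavior_saliences, orig.behavior_saliences)
        boots[b] = model.brain_saliences @ q
    mean = boots.mean(axis=0)
    se = boots.std(axis=0, ddof=1)
    return np.divide(mean, se, out=np.zeros_like(mean), where=se > 0)


def scalp_scores(brain: np.ndarray, brain_saliences: np.ndarray) -> np.ndarray:
    """Observation-wise expression of each LV: brain row · brain salience."""
    return brain @ brain_saliences


def delta_scalp_vs_exposure(
    scores: np.ndarray,
    rows: pd.DataFrame,
    exposure: pd.Series,
    n_boot: int = 500,
    seed: int | np.random.SeedSequence = 0,
) -> dict:
    """Pearson test of wCHI against the pre→post change in scalp scores."""
    frame = rows.assign(score=scores).pivot(
        index="subject_id", columns="session", values="score"
    )
    delta = (frame["post"] - frame["pre"]).reindex(exposure.index)
    if delta.isna().any():
        raise ValueError("scalp scores missing for some subjects")
    return pearson_with_bootstrap(exposure.to_numpy(), delta.to_numpy(), n_boot, seed)


def band_bootstrap_summary(
    bootstrap_ratios: np.ndarray,
    col_info: pd.DataFrame,
    block: str = "dwpli",
    threshold: float = BOOTSTRAP_RATIO_THRESHOLD,
) -> dict[str, float]:
    """Per-band mean of significant (|ratio| > threshold) signed ratios.

    Summarizes, per frequency band, how strongly the chosen block's columns
    contribute to the LV; a band with no significant columns yields 0.
    """
    ratios = np.asarray(bootstrap_ratios)
    out = {}
    for band, (lo, hi) in BANDS.items():
        sel = (
            (col_info["block"] == block)
            & (col_info["freq"] >= lo)
            & (col_info["freq"] <= hi)
        ).to_numpy()
        vals = ratios[sel]
        sig = np.abs(vals) > threshold
        if not sig.any():
            warnings.warn(f"no significant bootstrap ratios in band {band!r}", stacklevel=2)
            out[band] = 0.0
        else:
            out[band] = float(vals[sig].mean())
    return out


def run_behavioral_pls(
    brain: np.ndarray,
    behavior: np.ndarray,
    rows: pd.DataFrame,
    n_perm: int = 1000,
    n_boot: int = 500,
    seed: int | np.random.SeedSequence = 0,
) -> PLSModel:
    """Full rotated behavioral PLS: SVD, permutation p, bootstrap ratios,
    scalp scores."""
    conditions = rows["session"].to_numpy()
    subject_ids = rows["subject_id"].to_numpy()
    seeds = np.random.SeedSequence(seed).spawn(2) if isinstance(seed, int) else seed.spawn(2)
    model = svd_pls(stacked_correlation(brain, behavior, conditions))
    model.perm_p = permutation_test(brain, behavior, conditions, n_perm, seeds[0])
    model.bootstrap_ratios = bootstrap_saliences(
        brain, behavior, conditions, subject_ids, n_boot, seeds[1]
    )
    model.scalp_scores = scalp_scores(brain, model.brain_saliences)
    return model
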