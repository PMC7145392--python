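"""End-to-end drivers: cohort → preprocessing → connectivity → dose/PLS.

Thin orchestration over the stage modules so analysis scripts, tests and
reproduction runs share one code path.  All randomness (surrogates,
bootstraps, permutations) fans out from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from headnet import dose as _dose
from headnet import graphs as _graphs
from headnet import pls as _pls
from headnet import preprocess as _pre
from headnet import spectral as _spec
from headnet.synthetic import Cohort

__all__ = ["RecordingResult", "CohortAnalysis", "analyze_recording", "analyze_cohort", "dose_response_table", "behavioral_pls_on_cohort"]


@dataclass
class RecordingResult:
    spd: np.ndarray  # channel x frequency, percent
    tensors: dict  # measure -> ConnectivityTensor (with thresholds)
    band_fc: dict  # measure -> {band: whole-head value}
    spd_bands: dict  # band -> mean SPD%
    screen: _pre.ScreenResult
    labels: list[str]
    freqs: np.ndarray


def analyze_recording(
    recording: _pre.Recording,
    positions: np.ndarray,
    n_surrogates: int = 200,
    seed: int | np.random.SeedSequence = 0,
    measures: tuple[str, ...] = ("dwpli",),
    mode: str = "survivors-mean",
    n_keep: int = 40,
    apply_laplacian: bool = True,
    ridge_channels: list[str] | None = None,
) -> RecordingResult:
    """One recording through the full spectral/connectivity stage.

    ``n_surrogates = 0`` skips the null (tensors keep ``thresholds=None``
    and every cell counts as suprathreshold).
    """
    epochs, screen = _pre.preprocess_recording(
        recording,
        positions,
        ridge_channels=ridge_channels,
        n_keep=n_keep,
        apply_laplacian=apply_laplacian,
    )
    spectra = _spec.multitaper_fft(epochs)
    spd = _spec.spd_normalized(_spec.power_spectra(spectra))
    spd_bands = {
        band: float(spd[:, _spec.band_mask(spectra.freqs, band)].mean())
        for band in _spec.BANDS
    }
    seeds = np.random.SeedSequence(seed).spawn(len(measures)) if isinstance(seed, int) else seed.spawn(len(measures))
    tensors, band_fc = {}, {}
    for measure, sub_seed in zip(measures, seeds):
        tensor = _spec.connectivity(spectra, measure)
        if n_surrogates:
            tensor.thresholds = _spec.surrogate_null(epochs, n_surrogates, measure, sub_seed)
        tensors[measure] = tensor
        band_fc[measure] = _spec.threshold_and_band_average(tensor, mode=mode)
    return RecordingResult(
        spd=spd,
        tensors=tensors,
        band_fc=band_fc,
        spd_bands=spd_bands,
        screen=screen,
        labels=list(epochs.labels),
        freqs=spectra.freqs,
    )


@dataclass
class CohortAnalysis:
    results: dict  # (subject, session) -> RecordingResult
    band_table: pd.DataFrame  # subject, session, metric ("measure:band"), value
    graph_table: pd.DataFrame | None


def analyze_cohort(
    cohort: Cohort,
    n_surrogates: int = 100,
    seed: int | np.random.SeedSequence = 0,
    measures: tuple[str, ...] = ("dwpli",),
    mode: str = "survivors-mean",
    n_keep: int = 40,
    apply_laplacian: bool = True,
    graph_measure: str | None = "dwpli",
) -> CohortAnalysis:
    """All recordings of a cohort through the spectral stage, plus per-band
    whole-head FC / SPD summaries and (optionally) weighted graph metrics."""
    keys = sorted(cohort.eeg)
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    rec_seeds = ss.spawn(len(keys))
    results, band_rows, graph_rows = {}, [], []
    for key, rec_seed in zip(keys, rec_seeds):
        subject, session = key
        res = analyze_recording(
            cohort.eeg[key],
            cohort.positions,
            n_surrogates=n_surrogates,
            seed=rec_seed,
            measures=measures,
            mode=mode,
            n_keep=n_keep,
            apply_laplacian=apply_laplacian,
        )
        results[key] = res
        for measure in measures:
            for band, value in res.band_fc[measure].items():
                band_rows.append(
                    {"subject_id": subject, "session": session, "metric": f"{measure}:{band}", "value": value}
                )
        for band, value in res.spd_bands.items():
            band_rows.append(
                {"subject_id": subject, "session": session, "metric": f"spd:{band}", "value": value}
            )
        if graph_measure is not None:
            tensor = res.tensors[graph_measure]
            for band in _spec.BANDS:
                adj = _spec.band_adjacency(tensor, band, mode=mode)
                if not np.any(adj > 0):
                    continue
                metrics = _graphs.compute_metrics(adj)
                for name in ("charpath", "clustering_mean", "betweenness_max", "global_efficiency"):
                    graph_rows.append(
                        {
                            "subject_id": subject,
                            "session": session,
                            "metric": f"{name}:{band}",
                            "value": getattr(metrics, name),
                        }
                    )
    band_table = pd.DataFrame(band_rows)
    graph_table = pd.DataFrame(graph_rows) if graph_rows else None
    return CohortAnalysis(results=results, band_table=band_table, graph_table=graph_table)


def _session_pivot(table: pd.DataFrame, session: str) -> pd.DataFrame:
    sel = table[table["session"] == session]
    return sel.pivot(index="subject_id", columns="metric", values="value")


def dose_response_table(
    analysis_table: pd.DataFrame,
    exposure: pd.Series,
    n_boot: int = 500,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Exposure vs post−pre change for every metric in a long summary table."""
    pre = _session_pivot(analysis_table, "pre")
    post = _session_pivot(analysis_table, "post")
    common = pre.columns.intersection(post.columns)
    deltas = _dose.delta_metrics(pre[common], post[common])
    return _dose.correlate_exposure(deltas, exposure, n_boot=n_boot, seed=seed)


def behavioral_pls_on_cohort(
    cohort: Cohort,
    analysis: CohortAnalysis,
    n_perm: int = 500,
    n_boot: int = 200,
    seed: int | np.random.SeedSequence = 0,
    measures_in_brain: tuple[str, str] = ("dwpli", "coh"),
) -> dict:
    """Assemble brain/behavior matrices from a cohort analysis and run the
    behavioral PLS, including the Δscalp-score vs exposure follow-up."""
    from headnet import behavior as _behavior

    subjects = sorted({k[0] for k in analysis.results})
    some = analysis.results[(subjects[0], "pre")]
    pairs = some.tensors[measures_in_brain[0]].pairs
    dwpli_d, coh_d, spd_d = {}, {}, {}
    for key, res in analysis.results.items():
        dwpli_d[key] = res.tensors[measures_in_brain[0]].values
        coh_d[key] = (
            res.tensors[measures_in_brain[1]].values
            if measures_in_brain[1] in res.tensors
            else np.zeros_like(res.tensors[measures_in_brain[0]].values)
        )
        spd_d[key] = res.spd
    brain, rows, cols = _pls.assemble_brain_matrix(
        dwpli_d, coh_d, spd_d, subjects, pairs, some.labels, some.freqs
    )
    wrti = _behavior.score_trials(cohort.trials)
    wrti_wide = wrti.pivot(index=["subject_id", "session"], columns="task", values="wrti")
    behavior_mat = np.array(
        [
            wrti_wide.loc[(r.subject_id, r.session), list(_pls.BEHAVIOR_COLUMNS)]
            for r in rows.itertuples()
        ],
        dtype=float,
    )
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    pls_seed, follow_seed = ss.spawn(2)
    model = _pls.run_behavioral_pls(brain, behavior_mat, rows, n_perm=n_perm, n_boot=n_boot, seed=pls_seed)
    follow = _pls.delta_scalp_vs_exposure(
        model.scalp_scores[:, 0], rows, cohort.exposure["wchi"], seed=follow_seed
    )
    band_ratios = _pls.band_bootstrap_summary(model.bootstrap_ratios[:, 0], cols)
    return {
        "model": model,
        "rows": rows,
        "cols": cols,
        "brain": brain,
        "behavior": behavior_mat,
        "delta_scalp_vs_wchi": follow,
        "band_bootstrap_summary": band_ratios,
    }
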