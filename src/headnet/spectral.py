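"""Multitaper spectra, SPD, coherence/dWPLI connectivity, surrogate null.

Spectral estimation uses discrete prolate spheroidal sequence (DPSS)
multitapers on 2-s epochs with ±3 Hz frequency smoothing: time–half-bandwidth
NW = 2 s × 3 Hz = 6 and K = 2·NW − 1 = 11 tapers.  Fourier coefficients are
retained at the 99 analysis bins, 1–50 Hz in 0.5 Hz steps.

Connectivity between channel pairs is estimated from the complex
cross-spectrum pooled over epochs and tapers (440 observations at the study
design of 40 epochs × 11 tapers):

* coherence (COH): magnitude-squared, |⟨S_xy⟩|² / (⟨S_xx⟩⟨S_yy⟩) — sensitive
  to amplitude and phase, and inflated by zero-lag volume conduction;
* debiased weighted phase-lag index (dWPLI): with I_j = Im(S_xy) per
  observation,

      dWPLI = [ (Σ I_j)² − Σ I_j² ] / [ (Σ |I_j|)² − Σ I_j² ],

  defined as 0 when the denominator vanishes (all I_j = 0, e.g. identical
  signals).  Built only from the imaginary cross-spectrum and debiased for
  sample size, dWPLI is invariant to instantaneous linear mixing of
  independent sources.  Slightly negative estimates are retained, not
  clipped.

Spurious connectivity is controlled with a surrogate-data null: each
channel's amplitude series is split at a random point and the order of both
halves reversed (independently per channel), destroying cross-channel phase
relations while preserving each channel's amplitude distribution; the
observed value must exceed the 95th percentile of the surrogate
distribution at the same pair and frequency to count as significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import dpss

from headnet.preprocess import EpochArray

__all__ = [
    "BANDS",
    "FREQS",
    "TaperedSpectra",
    "ConnectivityTensor",
    "multitaper_fft",
    "power_spectra",
    "spd_normalized",
    "channel_pairs",
    "connectivity",
    "coherence",
    "dwpli",
    "split_reverse_surrogate",
    "surrogate_null",
    "band_mask",
    "threshold_and_band_average",
    "band_adjacency",
]

#: Analysis band edges in Hz (inclusive on both sides at the 0.5 Hz grid).
BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.5, 7.0),
    "alpha": (7.5, 15.0),
    "beta": (15.5, 30.0),
    "gamma": (30.5, 50.0),
}

#: The 99 analysis frequencies: 1–50 Hz in 0.5 Hz steps.
FREQS = np.arange(1.0, 50.0001, 0.5)

NW = 6.0  # time-half-bandwidth: 2 s x 3 Hz smoothing
N_TAPERS = 11  # 2*NW - 1


@dataclass
class TaperedSpectra:
    """DPSS Fourier coefficients: epochs × tapers × channels × frequencies."""

    coefficients: np.ndarray
    freqs: np.ndarray
    fs: float
    labels: list[str]

    @property
    def n_observations(self) -> int:
        return self.coefficients.shape[0] * self.coefficients.shape[1]


@dataclass
class ConnectivityTensor:
    """Pairwise connectivity (pair × frequency) with optional null thresholds."""

    measure: str
    values: np.ndarray
    pairs: list[tuple[str, str]]
    freqs: np.ndarray
    thresholds: np.ndarray | None = None

    @property
    def suprathreshold_mask(self) -> np.ndarray:
        if self.thresholds is None:
            return np.ones_like(self.values, dtype=bool)
        return self.values > self.thresholds


def multitaper_fft(epochs: EpochArray, nw: float = NW, n_tapers: int = N_TAPERS) -> TaperedSpectra:
    """DPSS-tapered Fourier coefficients at the 99 analysis bins.

    Requires 2-s epochs (0.5 Hz native resolution); tapers are unit-energy,
    so taper-averaged |coefficient|² scaled by 2/fs is a one-sided power
    density in µV²/Hz.
    """
    n_samples = epochs.data.shape[2]
    if abs(n_samples / epochs.fs - 2.0) > 1e-9:
        raise ValueError("multitaper analysis requires 2-s epochs (0.5 Hz bins)")
    tapers = dpss(n_samples, nw, Kmax=n_tapers)  # (K, S), unit energy
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / epochs.fs)
    idx = np.searchsorted(freqs, FREQS)
    if not np.allclose(freqs[idx], FREQS):
        raise ValueError("epoch length incompatible with the 0.5 Hz bin grid")
    tapered = epochs.data[:, None, :, :] * tapers[None, :, None, :]
    coeffs = np.fft.rfft(tapered, axis=3)[..., idx]
    return TaperedSpectra(coeffs, FREQS.copy(), epochs.fs, list(epochs.labels))


def power_spectra(spectra: TaperedSpectra) -> np.ndarray:
    """One-sided power density (channels × frequencies, µV²/Hz), averaged
    over epochs and tapers."""
    return (2.0 / spectra.fs) * np.mean(np.abs(spectra.coefficients) ** 2, axis=(0, 1))


def spd_normalized(power: np.ndarray) -> np.ndarray:
    """Normalized spectral power density in percent.

    SPD%(c, f) = 100 · P(c, f) / mean_f P(c, f); each channel's SPD averages
    to exactly 100% over the 99 bins and is invariant to channel gain.
    """
    mean_power = power.mean(axis=-1, keepdims=True)
    if np.any(mean_power == 0):
        raise ValueError("all-zero channel: SPD undefined")
    return 100.0 * power / mean_power


def channel_pairs(labels: list[str]) -> list[tuple[str, str]]:
    """Unordered channel pairs in row-major (i < j) order."""
    return [(labels[i], labels[j]) for i in range(len(labels)) for j in range(i + 1, len(labels))]


def _pair_indices(n_channels: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n_channels, k=1)
    return iu[0], iu[1]


def connectivity(
    spectra: TaperedSpectra, measure: str, chunk: int = 128
) -> ConnectivityTensor:
    """All-pairs COH or dWPLI from pooled epoch×taper observations."""
    x = spectra.coefficients
    n_obs = x.shape[0] * x.shape[1]
    if n_obs < 2:
        raise ValueError("connectivity needs at least 2 epoch x taper observations")
    obs = x.reshape(n_obs, x.shape[2], x.shape[3])  # (obs, chan, freq)
    ii, jj = _pair_indices(obs.shape[1])
    n_pairs = len(ii)
    n_freq = obs.shape[2]
    out = np.empty((n_pairs, n_freq))
    if measure == "coh":
        auto = np.mean(np.abs(obs) ** 2, axis=0)  # (chan, freq)
        if np.any(auto == 0):
            raise ValueError("zero auto-spectrum")
        for start in range(0, n_pairs, chunk):
            sl = slice(start, start + chunk)
            sxy = np.mean(obs[:, ii[sl], :] * np.conj(obs[:, jj[sl], :]), axis=0)
            out[sl] = np.abs(sxy) ** 2 / (auto[ii[sl]] * auto[jj[sl]])
    elif measure == "dwpli":
        for start in range(0, n_pairs, chunk):
            sl = slice(start, start + chunk)
            cross = obs[:, ii[sl], :] * np.conj(obs[:, jj[sl], :])
            imag = cross.imag.copy()
            # imaginary parts at machine-precision level (e.g. identical
            # signals) are exact zeros contaminated by rounding; keep them 0
            imag[np.abs(imag) <= 1e-12 * np.abs(cross)] = 0.0
            s1 = imag.sum(axis=0)
            s2 = (imag**2).sum(axis=0)
            sabs = np.abs(imag).sum(axis=0)
            num = s1**2 - s2
            denom = sabs**2 - s2
            out[sl] = np.divide(num, denom, out=np.zeros_like(num), where=denom != 0)
    else:
        raise ValueError(f"unknown measure {measure!r}")
    return ConnectivityTensor(measure, out, channel_pairs(spectra.labels), spectra.freqs.copy())


def _single_pair(spectra: TaperedSpectra, pair: tuple[str, str], measure: str) -> np.ndarray:
    labels = spectra.labels
    i, j = labels.index(pair[0]), labels.index(pair[1])
    sub = TaperedSpectra(
        spectra.coefficients[:, :, [i, j], :], spectra.freqs, spectra.fs, [pair[0], pair[1]]
    )
    return connectivity(sub, measure).values[0]


def coherence(spectra: TaperedSpectra, pair: tuple[str, str]) -> np.ndarray:
    """Magnitude-squared coherence for one channel pair (frequency vector)."""
    return _single_pair(spectra, pair, "coh")


def dwpli(spectra: TaperedSpectra, pair: tuple[str, str]) -> np.ndarray:
    """Debiased WPLI for one channel pair (frequency vector)."""
    return _single_pair(spectra, pair, "dwpli")


def split_reverse_surrogate(continuous: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Split-and-reverse surrogate of a channels × samples array.

    For each channel independently a split index is drawn uniformly from
    [0.1·N, 0.9·N] (avoiding degenerate, no-op splits) and the sample order
    of both halves is reversed.  The per-channel amplitude histogram is
    preserved exactly; cross-channel phase relations are destroyed.
    """
    n = continuous.shape[1]
    lo, hi = int(np.ceil(0.1 * n)), int(np.floor(0.9 * n))
    out = np.empty_like(continuous)
    splits = rng.integers(lo, hi + 1, size=continuous.shape[0])
    for c, k in enumerate(splits):
        out[c, :k] = continuous[c, k - 1 :: -1]
        out[c, k:] = continuous[c, : k - 1 : -1]
    return out


def surrogate_null(
    epochs: EpochArray,
    n_surrogates: int = 1000,
    measure: str = "dwpli",
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """95th-percentile surrogate thresholds, pair × frequency.

    Surrogates are built on the continuous concatenation of the selected
    epochs (split-reverse per channel), re-epoched, and passed through the
    same multitaper/connectivity estimator as the observed data.
    """
    if n_surrogates < 20:
        raise ValueError("need at least 20 surrogates for a 95th percentile")
    rng = np.random.default_rng(seed)
    e, c, s = epochs.data.shape
    continuous = epochs.data.transpose(1, 0, 2).reshape(c, e * s)
    null = None
    for k in range(n_surrogates):
        surr = split_reverse_surrogate(continuous, rng)
        surr_epochs = EpochArray(
            surr.reshape(c, e, s).transpose(1, 0, 2),
            epochs.fs,
            list(epochs.labels),
            epochs.epoch_seconds,
        )
        values = connectivity(multitaper_fft(surr_epochs), measure).values
        if null is None:
            null = np.empty((n_surrogates,) + values.shape)
        null[k] = values
    return np.percentile(null, 95.0, axis=0)


def band_mask(freqs: np.ndarray, band: str) -> np.ndarray:
    lo, hi = BANDS[band]
    return (freqs >= lo) & (freqs <= hi)


def threshold_and_band_average(
    tensor: ConnectivityTensor, mode: str = "survivors-mean"
) -> dict[str, float]:
    """Whole-head band-averaged connectivity from a thresholded tensor.

    ``survivors-mean`` averages suprathreshold values only; ``zeroed-mean``
    sets subthreshold cells to 0 and averages over all pair × bin cells.  A
    band with no suprathreshold cells yields 0.
    """
    if mode not in ("survivors-mean", "zeroed-mean"):
        raise ValueError(f"unknown mode {mode!r}")
    mask = tensor.suprathreshold_mask
    out = {}
    for band in BANDS:
        fsel = band_mask(tensor.freqs, band)
        vals = tensor.values[:, fsel]
        supra = mask[:, fsel]
        if not supra.any():
            import warnings

            warnings.warn(f"no suprathreshold cells in band {band!r}", stacklevel=2)
            out[band] = 0.0
        elif mode == "survivors-mean":
            out[band] = float(vals[supra].mean())
        else:
            out[band] = float(np.where(supra, vals, 0.0).mean())
    return out


def band_adjacency(tensor: ConnectivityTensor, band: str, mode: str = "survivors-mean") -> np.ndarray:
    """Symmetric, zero-diagonal weight matrix of band-averaged thresholded FC.

    Per pair: mean of in-band suprathreshold values (``survivors-mean``) or
    mean with subthreshold bins zeroed (``zeroed-mean``); pairs with no
    suprathreshold bins get weight 0.  Slightly negative dWPLI survivors are
    clipped at 0 so the result is a valid non-negative edge weight matrix.
    """
    fsel = band_mask(tensor.freqs, band)
    vals = tensor.values[:, fsel]
    supra = tensor.suprathreshold_mask[:, fsel]
    counts = supra.sum(axis=1)
    sums = np.where(supra, vals, 0.0).sum(axis=1)
    if mode == "survivors-mean":
        weights = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    elif mode == "zeroed-mean":
        weights = sums / fsel.sum()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    weights = np.clip(weights, 0.0, None)
    labels = list(dict.fromkeys(lab for pair in tensor.pairs for lab in pair))
    n = len(labels)
    index = {lab: k for k, lab in enumerate(labels)}
    adj = np.zeros((n, n))
    for (a, b), w in zip(tensor.pairs, weights):
        adj[index[a], index[b]] = adj[index[b], index[a]] = w
    return adj
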