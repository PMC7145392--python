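"""Multitaper spectra, SPD, coherence/dWPLI, surrogates, band averaging."""

import numpy as np
import pytest

from headnet.preprocess import EpochArray
from headnet.spectral import (
    BANDS,
    FREQS,
    ConnectivityTensor,
    band_adjacency,
    band_mask,
    channel_pairs,
    coherence,
    connectivity,
    dwpli,
    multitaper_fft,
    power_spectra,
    spd_normalized,
    split_reverse_surrogate,
    surrogate_null,
    threshold_and_band_average,
)

FS = 500.0


def epochs_from(data):
    labels = [f"C{i:02d}" for i in range(data.shape[1])]
    return EpochArray(data, FS, labels)


class TestMultitaper:
    def test_sinusoid_power_concentrated_in_smoothing_band(self):
        t = np.arange(1000) / FS
        data = np.tile(np.sin(2 * np.pi * 10.0 * t), (40, 1, 1))
        power = power_spectra(multitaper_fft(epochs_from(data)))
        peak = FREQS[np.argmax(power[0])]
        assert abs(peak - 10.0) <= 3.0
        inband = band_mask(FREQS, "alpha")  # 7.5-15 covers 10 +- 3
        assert power[0, inband].sum() / power[0].sum() > 0.95

    def test_white_noise_spectrum_flat(self, rng):
        data = rng.standard_normal((40, 1, 1000))
        power = power_spectra(multitaper_fft(epochs_from(data)))
        rel = power[0] / power[0].mean()
        # 40 epochs x 11 tapers: per-bin SE ~ 1/sqrt(440)
        assert np.abs(rel - 1.0).max() < 3 * 3 / np.sqrt(440)

    def test_parseval_within_five_percent(self, rng):
        # band-limited signal so the 1-50 Hz grid captures the variance
        from scipy.signal import sosfiltfilt, butter

        sos = butter(4, (5.0, 40.0), btype="bandpass", output="sos", fs=FS)
        data = sosfiltfilt(sos, rng.standard_normal(40_000)).reshape(40, 1, 1000)
        power = power_spectra(multitaper_fft(epochs_from(data)))
        integral = power[0].sum() * 0.5  # 0.5 Hz bins
        assert integral == pytest.approx(data.var(), rel=0.05)

    def test_wrong_epoch_length_rejected(self, rng):
        epochs = EpochArray(rng.standard_normal((5, 2, 500)), FS, ["a", "b"], epoch_seconds=1.0)
        with pytest.raises(ValueError):
            multitaper_fft(epochs)


class TestSpd:
    def test_flat_spectrum_gives_100_percent(self):
        assert np.allclose(spd_normalized(np.ones((3, 99))), 100.0)

    def test_mean_over_bins_is_100(self, rng):
        spd = spd_normalized(rng.random((4, 99)) + 0.1)
        np.testing.assert_allclose(spd.mean(axis=1), 100.0)

    def test_gain_invariance(self, rng):
        p = rng.random((2, 99)) + 0.1
        np.testing.assert_allclose(spd_normalized(p), spd_normalized(4.0 * p))

    def test_zero_channel_raises(self):
        with pytest.raises(ValueError):
            spd_normalized(np.zeros((1, 99)))


class TestCoherence:
    def test_self_coherence_is_one(self, noise_spectra):
        # duplicate channel: coherence with itself = 1 everywhere
        sub = noise_spectra.coefficients[:, :, [0, 0], :]
        from headnet.spectral import TaperedSpectra

        sp = TaperedSpectra(sub, noise_spectra.freqs, FS, ["x", "y"])
        np.testing.assert_allclose(coherence(sp, ("x", "y")), 1.0, atol=1e-12)

    def test_delayed_copy_fully_coherent(self, rng):
        x = rng.standard_normal(40 * 1000 + 10)
        data = np.stack([x[:-10], x[10:]]).reshape(2, 40, 1000).transpose(1, 0, 2)
        sp = multitaper_fft(epochs_from(data))
        coh = coherence(sp, ("C00", "C01"))
        assert coh.min() > 0.9

    def test_independent_noise_small_positive_bias(self, noise_spectra):
        coh = coherence(noise_spectra, ("C01", "C02"))
        # E[COH] ~ 1/n_obs for independent signals
        assert 0 < coh.mean() < 5.0 / noise_spectra.n_observations

    def test_bounds(self, noise_spectra):
        values = connectivity(noise_spectra, "coh").values
        assert values.min() >= 0.0 and values.max() <= 1.0


def dwpli_oracle(imag_obs):
    """Literal direct-summation form of the debiased WPLI."""
    s1 = sum(imag_obs)
    s2 = sum(i**2 for i in imag_obs)
    sabs = sum(abs(i) for i in imag_obs)
    denom = sabs**2 - s2
    return 0.0 if denom == 0 else (s1**2 - s2) / denom


class TestDwpli:
    def test_matches_literal_formula_oracle(self, noise_spectra):
        values = connectivity(noise_spectra, "dwpli").values
        obs = noise_spectra.coefficients.reshape(-1, 6, 99)
        for p_idx, (a, b) in enumerate(channel_pairs(noise_spectra.labels)[:3]):
            i, j = noise_spectra.labels.index(a), noise_spectra.labels.index(b)
            for f in (0, 50, 98):
                imag = [np.imag(obs[o, i, f] * np.conj(obs[o, j, f])) for o in range(obs.shape[0])]
                assert values[p_idx, f] == pytest.approx(dwpli_oracle(imag), abs=1e-12)

    def test_identical_signals_give_zero(self, rng):
        x = rng.standard_normal((40, 1, 1000))
        data = np.concatenate([x, x], axis=1)
        sp = multitaper_fft(epochs_from(data))
        np.testing.assert_allclose(dwpli(sp, ("C00", "C01")), 0.0, atol=1e-12)

    def test_constant_quarter_cycle_lag_gives_one(self):
        t = np.arange(1000) / FS
        rng = np.random.default_rng(0)
        epochs = []
        for _ in range(20):
            phase = rng.uniform(0, 2 * np.pi)
            x = np.sin(2 * np.pi * 10.0 * t + phase)
            y = np.sin(2 * np.pi * 10.0 * t + phase - np.pi / 2)
            epochs.append(np.stack([x, y]))
        sp = multitaper_fft(epochs_from(np.stack(epochs)))
        f10 = np.flatnonzero(FREQS == 10.0)[0]
        # spectral leakage into far-out tapers perturbs the identity at ~1e-4
        assert dwpli(sp, ("C00", "C01"))[f10] == pytest.approx(1.0, abs=1e-3)

    def test_independent_noise_near_zero(self, noise_spectra):
        assert abs(dwpli(noise_spectra, ("C03", "C04")).mean()) < 0.05

    def test_single_observation_rejected(self, noise_spectra):
        from headnet.spectral import TaperedSpectra

        sp = TaperedSpectra(
            noise_spectra.coefficients[:1, :1], noise_spectra.freqs, FS, noise_spectra.labels
        )
        with pytest.raises(ValueError):
            connectivity(sp, "dwpli")


class TestSurrogates:
    def test_amplitude_histogram_preserved_exactly(self, rng):
        x = rng.standard_normal((3, 5000))
        surr = split_reverse_surrogate(x, rng)
        for c in range(3):
            np.testing.assert_array_equal(np.sort(surr[c]), np.sort(x[c]))

    def test_deterministic_given_seed(self, noise_epochs):
        a = surrogate_null(noise_epochs, 20, "dwpli", 7)
        b = surrogate_null(noise_epochs, 20, "dwpli", 7)
        np.testing.assert_array_equal(a, b)

    def test_planted_coupling_exceeds_threshold(self):
        from headnet.synthetic import CouplingSpec, gen_coupled_eeg
        from headnet.preprocess import epoch_and_detrend, select_epochs_by_gfp

        rec = gen_coupled_eeg(
            4, 100.0, FS, [CouplingSpec(("C01", "C02"), "theta", np.pi / 2, 2.0)], seed=3
        )
        epochs = select_epochs_by_gfp(epoch_and_detrend(rec), 40)
        sp = multitaper_fft(epochs)
        tensor = connectivity(sp, "dwpli")
        thr = surrogate_null(epochs, 30, "dwpli", 11)
        pair = channel_pairs(epochs.labels).index(("C01", "C02"))
        theta = band_mask(FREQS, "theta")
        assert (tensor.values[pair, theta] > thr[pair, theta]).all()

    def test_too_few_surrogates_rejected(self, noise_epochs):
        with pytest.raises(ValueError):
            surrogate_null(noise_epochs, 5, "dwpli", 0)


def toy_tensor(values, thresholds, freqs):
    n = values.shape[0]
    labels = [f"C{i}" for i in range(int((1 + np.sqrt(1 + 8 * n)) / 2))]
    return ConnectivityTensor("dwpli", values, channel_pairs(labels), np.asarray(freqs), thresholds)


@pytest.mark.filterwarnings("ignore:no suprathreshold cells")
class TestBandAveraging:
    def test_all_suprathreshold_equals_plain_mean(self, rng):
        values = rng.random((3, 4))
        tensor = toy_tensor(values, np.zeros((3, 4)) - 1, [2.0, 3.0, 5.0, 6.0])
        out_s = threshold_and_band_average(tensor, "survivors-mean")
        out_z = threshold_and_band_average(tensor, "zeroed-mean")
        assert out_s["delta"] == pytest.approx(values[:, :2].mean())
        assert out_z["delta"] == pytest.approx(values[:, :2].mean())

    def test_half_suprathreshold_modes_differ(self):
        values = np.full((2, 2), 0.6)
        thr = np.array([[0.0, 1.0], [0.0, 1.0]])  # half the cells survive
        tensor = toy_tensor(values, thr, [2.0, 3.0])
        assert threshold_and_band_average(tensor, "survivors-mean")["delta"] == pytest.approx(0.6)
        assert threshold_and_band_average(tensor, "zeroed-mean")["delta"] == pytest.approx(0.3)

    def test_matches_brute_force_enumeration(self, rng):
        values = rng.standard_normal((3, 4)) * 0.3
        thr = rng.standard_normal((3, 4)) * 0.1
        freqs = [2.0, 3.0, 5.0, 6.5]
        tensor = toy_tensor(values, thr, freqs)
        out = threshold_and_band_average(tensor, "survivors-mean")
        for band, (lo, hi) in (("delta", (1, 4)), ("theta", (4.5, 7))):
            cells = [
                values[p, f]
                for p in range(3)
                for f in range(4)
                if lo <= freqs[f] <= hi and values[p, f] > thr[p, f]
            ]
            assert out[band] == pytest.approx(np.mean(cells))

    def test_empty_band_warns_and_returns_zero(self):
        values = np.zeros((1, 2))
        tensor = toy_tensor(values, np.ones((1, 2)), [10.0, 20.0])
        with pytest.warns(UserWarning):
            out = threshold_and_band_average(tensor)
        assert out["delta"] == 0.0

    def test_linearity_of_band_averages(self, rng):
        values = rng.random((3, 4))
        tensor = toy_tensor(values, np.zeros((3, 4)), [2.0, 3.0, 5.0, 6.0])
        scaled = toy_tensor(2 * values, np.zeros((3, 4)), [2.0, 3.0, 5.0, 6.0])
        a = threshold_and_band_average(tensor)
        b = threshold_and_band_average(scaled)
        for band in ("delta", "theta"):
            assert b[band] == pytest.approx(2 * a[band])

    def test_band_adjacency_is_symmetric_with_zero_diagonal(self, rng):
        values = rng.random((3, 4))
        tensor = toy_tensor(values, np.zeros((3, 4)) - 1, [2.0, 3.0, 5.0, 6.0])
        adj = band_adjacency(tensor, "delta")
        assert adj.shape == (3, 3)
        np.testing.assert_allclose(adj, adj.T)
        assert np.all(np.diag(adj) == 0)
        assert adj[0, 1] == pytest.approx(values[0, :2].mean())


def test_band_edges_cover_expected_bin_counts():
    counts = {b: band_mask(FREQS, b).sum() for b in BANDS}
    assert counts == {"delta": 7, "theta": 6, "alpha": 16, "beta": 30, "gamma": 40}
    assert sum(counts.values()) == 99
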