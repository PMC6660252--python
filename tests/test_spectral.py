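"""Spectral chain: notch design, Morlet CWT, binning, z-normalization."""

import math

import numpy as np
import pytest
from scipy.signal import freqz

from seegspeed import spectral
from seegspeed.spectral import (SpectralConfig, SpectralError, bin_power,
                                binned_cwt_power, cwt_power, design_notch,
                                exclude_artifact_channels, log_freq_grid,
                                morlet_scale, normalize_power, notch_filter)

FS = 2000.0


class TestNotch:
    def test_response_at_notch_and_edges(self):
        b, a = design_notch(FS)
        w = np.array([60.0, 58.5, 61.5, 10.0]) * 2 * np.pi / FS
        _, h = freqz(b, a, worN=w)
        mag = np.abs(h)
        assert mag[0] <= 1e-10  # unit-circle zero at 60 Hz
        target = 10 ** (-1 / 20)
        assert mag[1] == pytest.approx(target, abs=0.01)
        assert mag[2] == pytest.approx(target, abs=0.01)
        assert mag[3] > 0.99  # passband essentially untouched

    def test_60hz_tone_removed_10hz_kept(self):
        t = np.arange(int(6 * FS)) / FS
        edge = int(0.5 * FS)
        tone60 = np.sin(2 * np.pi * 60 * t)
        out = notch_filter(tone60, FS)[edge:-edge]
        assert np.sqrt(np.mean(out ** 2)) < 0.01 * np.sqrt(0.5)
        tone10 = np.sin(2 * np.pi * 10 * t)
        out10 = notch_filter(tone10, FS)[edge:-edge]
        assert np.sqrt(np.mean(out10 ** 2)) >= 0.99 * np.sqrt(0.5)

    def test_zero_signal_and_bad_fs(self):
        assert np.allclose(notch_filter(np.zeros(5000), FS), 0.0)
        with pytest.raises(SpectralError):
            design_notch(100.0)  # cannot notch 60 Hz at fs=100


class TestFreqGrid:
    def test_twelve_voices_one_to_two_hundred(self):
        freqs = log_freq_grid(SpectralConfig())
        assert freqs[0] == 1.0
        assert freqs[-1] <= 200.0
        assert len(freqs) == 92
        ratios = freqs[1:] / freqs[:-1]
        assert np.allclose(ratios, 2 ** (1 / 12))

    def test_scale_map_admissibility_corrected(self):
        # f·s = (ω0 + sqrt(2+ω0²))/(4π), within ~1.4% of ω0/(2π) for ω0=6
        s = morlet_scale(10.0, 6.0)
        assert s * 10.0 == pytest.approx((6 + math.sqrt(38)) / (4 * math.pi))
        assert s * 10.0 == pytest.approx(6 / (2 * math.pi), rel=0.015)


def _direct_morlet_conv(x, fs, freq, omega0=6.0):
    """Oracle: direct time-domain convolution with the sampled Morlet kernel
    h[m] = sqrt(dt/s)·pi^(-1/4)·exp(i·ω0·m·dt/s − (m·dt)²/(2s²))."""
    s = morlet_scale(freq, omega0)
    half = int(math.ceil(6 * s * fs))
    m = np.arange(-half, half + 1)
    t = m / fs
    h = (math.sqrt(1 / (fs * s)) * math.pi ** -0.25
         * np.exp(1j * omega0 * t / s - t ** 2 / (2 * s ** 2)))
    out = np.empty(x.size, dtype=complex)
    for n in range(x.size):
        lo = max(0, n - half)
        hi = min(x.size, n + half + 1)
        seg = x[lo:hi]
        ker = h[(lo - n) + half:(hi - n) + half]
        out[n] = seg @ ker
    return out


class TestCwt:
    config = SpectralConfig(freq_min=5.0)

    def test_peak_at_carrier(self):
        t = np.arange(8000) / FS
        x = np.sin(2 * np.pi * 10 * t)
        freqs, power = cwt_power(x, FS, self.config)
        mean_p = power[:, 1000:-1000].mean(axis=1)
        assert freqs[np.argmax(mean_p)] == pytest.approx(10.0, rel=2 ** (1 / 24))

    def test_two_tones_two_local_maxima(self):
        t = np.arange(8000) / FS
        x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 80 * t)
        freqs, power = cwt_power(x, FS, self.config)
        mean_p = power[:, 1000:-1000].mean(axis=1)
        local_max = [i for i in range(1, len(freqs) - 1)
                     if mean_p[i] > mean_p[i - 1] and mean_p[i] > mean_p[i + 1]]
        peak_freqs = sorted(freqs[i] for i in
                            sorted(local_max, key=lambda i: -mean_p[i])[:2])
        assert peak_freqs[0] == pytest.approx(10.0, rel=2 ** (1 / 24))
        assert peak_freqs[1] == pytest.approx(80.0, rel=2 ** (1 / 24))

    def test_homogeneity_power_quadruples(self, rng):
        x = rng.standard_normal(7000)
        _, p1 = cwt_power(x, FS, self.config)
        _, p2 = cwt_power(2 * x, FS, self.config)
        assert np.allclose(p2, 4 * p1, rtol=1e-6)

    def test_matches_direct_convolution(self, rng):
        x = rng.standard_normal(4000)  # 2 s
        freqs, power = cwt_power(x, FS, self.config)
        edge = 1200
        for idx in (0, 12, 30, 45, len(freqs) - 1):
            w = _direct_morlet_conv(x, FS, freqs[idx])
            ref = np.abs(w) ** 2
            got = power[idx]
            rel = (np.abs(got[edge:-edge] - ref[edge:-edge])
                   / np.maximum(ref[edge:-edge], ref.max() * 1e-12))
            assert rel.max() < 1e-4

    def test_grid_outside_nyquist_rejected(self):
        with pytest.raises(SpectralError):
            cwt_power(np.zeros(8000), 300.0, SpectralConfig(freq_min=5.0))

    def test_too_short_signal_rejected(self):
        with pytest.raises(SpectralError):
            cwt_power(np.zeros(500), FS, self.config)


class TestBinPower:
    def test_constant_power(self):
        p = np.full((1, 1000), 3.7)
        times, binned = bin_power(p, FS)
        assert np.allclose(binned, 3.7)

    def test_sample_index_ramp_closed_form(self):
        # mean of samples k-199..k is k - 99.5; labels every 100 samples
        p = np.arange(2000, dtype=float)[None, :]
        times, binned = bin_power(p, FS)
        k = (times * FS).round().astype(int)
        assert np.array_equal(k, np.arange(199, 2000, 100))
        assert np.allclose(binned[0], k - 99.5)
        # brute force on a couple of bins
        assert binned[0, 3] == pytest.approx(p[0, k[3] - 199:k[3] + 1].mean())

    def test_consecutive_bins_overlap_100_samples(self):
        times, _ = bin_power(np.ones((1, 1000)), FS)
        k = (times * FS).round().astype(int)
        # trailing 200-sample windows starting 100 apart share 100 samples
        assert np.all(np.diff(k) == 100)

    def test_too_short_session(self):
        with pytest.raises(SpectralError):
            bin_power(np.ones((1, 50)), FS)


class TestNormalize:
    def test_z_score_mean_zero_sd_one(self, rng):
        binned = np.exp(rng.standard_normal((5, 400)))
        spg = normalize_power(binned, np.arange(400) * 0.05, np.arange(5) + 1.0)
        assert np.abs(spg.values.mean(axis=0)).max() < 1e-9
        assert np.abs(spg.values.std(axis=0) - 1).max() < 1e-9

    def test_hand_computed_two_bins(self):
        # powers (e, e³): ln = (1, 3), population mean 2, population sd 1
        binned = np.array([[math.e, math.e ** 3]])
        spg = normalize_power(binned, np.array([0.1, 0.15]), np.array([10.0]))
        assert np.allclose(spg.values.ravel(), [-1.0, 1.0])

    def test_log_shift_invariance(self, rng):
        binned = np.exp(rng.standard_normal((3, 200)))
        a = normalize_power(binned, np.arange(200.0), np.arange(3.0) + 1)
        b = normalize_power(binned * 10, np.arange(200.0), np.arange(3.0) + 1)
        assert np.allclose(a.values, b.values)

    def test_nonpositive_and_zero_variance_rejected(self):
        with pytest.raises(SpectralError):
            normalize_power(np.array([[1.0, -1.0]]), np.arange(2.0),
                            np.array([5.0]))
        with pytest.raises(SpectralError, match="8.5"):
            normalize_power(np.ones((1, 10)), np.arange(10.0), np.array([8.5]),
                            channel="ch03")


class TestFastPathEquivalence:
    def test_decimated_path_matches_reference(self, small_session):
        sig = notch_filter(small_session.signal[1], small_session.fs)
        freqs, power = cwt_power(sig, small_session.fs)
        _, ref = bin_power(power, small_session.fs)
        freqs2, _, fast = binned_cwt_power(sig, small_session.fs)
        assert np.array_equal(freqs, freqs2)
        assert np.max(np.abs(fast - ref) / ref) < 2e-4

    def test_deterministic_bit_pattern(self, small_session):
        sig = small_session.signal[0]
        _, _, a = binned_cwt_power(sig, small_session.fs)
        _, _, b = binned_cwt_power(sig, small_session.fs)
        assert np.array_equal(a, b)


class TestExcludeChannels:
    names = ["ch00", "ch01", "ch02", "ch03"]

    def test_empty_list_keeps_all(self):
        assert exclude_artifact_channels(self.names) == tuple(self.names)

    def test_exclusion_and_flags(self):
        kept = exclude_artifact_channels(self.names, exclude=["ch01"],
                                         artifact_flags=[False, False, True, False])
        assert kept == ("ch00", "ch03")

    def test_unknown_name_rejected(self):
        with pytest.raises(SpectralError, match="chXX"):
            exclude_artifact_channels(self.names, exclude=["chXX"])

    def test_no_channels_remain(self):
        with pytest.raises(SpectralError, match="no channels remain"):
            exclude_artifact_channels(self.names, exclude=self.names)

    def test_feature_pool_shrinks_by_six_per_channel(self, small_session,
                                                     small_spectrograms):
        from seegspeed import behavior, features
        st, _ = behavior.build_trial_speed_table(small_session.trial_table)
        modeled = small_session.trial_table.set_index("trial_id").loc[
            st["trial_id"]].reset_index()
        spg = {k: v for k, v in small_spectrograms.items() if k != "ch00"}
        fm = features.build_feature_matrix(small_session, spg, modeled)
        assert fm.n_features == (4 - 1) * 6
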