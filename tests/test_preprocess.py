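"""Denoising chain: DC removal, short-time spectra, spectral
subtraction, band-pass reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurovowel.eeg_io import EEGRecording
from neurovowel.preprocess import (
    BandSpec,
    FrameSpec,
    NoiseProfile,
    bandpass_reconstruct,
    estimate_noise_profile,
    preprocess,
    remove_dc_bias,
    spectral_subtract,
    stft_frames,
)


def _rec(x, fs=512.0):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return EEGRecording(x, fs)


class TestRemoveDcBias:
    def test_constant_becomes_zero(self):
        out = remove_dc_bias(_rec(np.full(512, 5.0)))
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_hand_example_block_of_two(self):
        # blocks [1,2] and [3,4]: means 1.5 and 3.5
        out = remove_dc_bias(_rec([1.0, 2.0, 3.0, 4.0]), block_ms=2 / 512 * 1000)
        np.testing.assert_allclose(out.samples[0], [-0.5, 0.5, -0.5, 0.5])

    def test_block_means_vanish_on_noise(self, rng):
        out = remove_dc_bias(_rec(rng.standard_normal(1024) + 7.0))
        block = round(0.1 * 512)
        for s in range(0, 1024, block):
            assert abs(out.samples[0, s : s + block].mean()) < 1e-12

    def test_rejects_bad_block(self):
        with pytest.raises(ValueError):
            remove_dc_bias(_rec(np.ones(10)), block_ms=0)


class TestStftFrames:
    def test_default_zero_pad_is_104_points(self):
        spec = FrameSpec()
        assert spec.zero_pad == 104
        assert spec.window_len == 24 and spec.hop == 12 and spec.n_fft == 128

    def test_freq_resolution_is_4hz(self):
        assert FrameSpec().freq_resolution == 4.0

    def test_tone_concentrates_at_its_bin(self):
        # 120 Hz on the 4 Hz grid -> bin 30
        t = np.arange(4096) / 512.0
        spg = stft_frames(_rec(np.sin(2 * np.pi * 120.0 * t)))
        mags = np.abs(spg.values[0])
        assert np.all(np.argmax(mags, axis=1) == 30)

    def test_zero_input_zero_spectrogram(self):
        spg = stft_frames(_rec(np.zeros(256)))
        assert np.all(spg.values == 0)

    def test_too_short_recording_raises(self):
        with pytest.raises(ValueError):
            stft_frames(_rec(np.zeros(10)))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(n=st.integers(min_value=24, max_value=5000))
    def test_frame_count_closed_form(self, n):
        spec = FrameSpec()
        spg = stft_frames(_rec(np.zeros(n)), spec)
        assert spg.n_frames == (n - spec.window_len) // spec.hop + 1


class TestNoiseProfile:
    def test_single_frame_profile_is_that_frame(self, noise_recording):
        spg = stft_frames(noise_recording)
        prof = estimate_noise_profile(spg, (3, 4))
        np.testing.assert_allclose(prof.mean_magnitude, np.abs(spg.values[:, 3, :]))

    def test_mean_of_two_values(self):
        spec = FrameSpec()
        values = np.zeros((1, 2, spec.n_bins), dtype=complex)
        values[0, 0, 5] = 2.0
        values[0, 1, 5] = 4.0
        spg_like = stft_frames(_rec(np.zeros(48)))
        spg_like.values = values
        prof = estimate_noise_profile(spg_like, (0, 2))
        assert prof.mean_magnitude[0, 5] == pytest.approx(3.0)

    def test_stationary_noise_matches_analytic_level(self, rng):
        # white noise sigma=1: E|X(k)|^2 = sigma^2 * sum(w^2) at interior bins,
        # |X| is Rayleigh with mean sqrt(pi/4 * E|X|^2)
        sigma = 1.0
        rec = _rec(rng.standard_normal(24 * 4000) * sigma)
        spec = FrameSpec()
        spg = stft_frames(rec, spec)
        prof = estimate_noise_profile(spg, (0, spg.n_frames))
        w2 = np.sum(spec.window() ** 2)
        expected = np.sqrt(np.pi / 4.0 * sigma**2 * w2)
        mid = prof.mean_magnitude[0, 10:55]
        se = expected * 0.53 / np.sqrt(spg.n_frames)  # Rayleigh cv ~ 0.52
        assert np.all(np.abs(mid - expected) < 3 * se + 0.05 * expected)

    def test_empty_range_raises(self, noise_recording):
        spg = stft_frames(noise_recording)
        with pytest.raises(ValueError):
            estimate_noise_profile(spg, (5, 5))


class TestSpectralSubtract:
    def test_equal_noise_zeroes_everything(self, noise_recording):
        spg = stft_frames(noise_recording)
        noise = NoiseProfile(np.abs(spg.values[:, 0, :]), 1)
        out = spectral_subtract(spg, noise)
        assert np.all(np.abs(out.values[:, 0, :]) < 1e-12)

    def test_rectification_floor(self):
        spg = stft_frames(_rec(np.zeros(48)))
        spg.values = np.full((1, spg.n_frames, spg.spec.n_bins), 1.0 + 0j)
        noise = NoiseProfile(np.full((1, spg.spec.n_bins), 2.0), 1)
        out = spectral_subtract(spg, noise)
        assert np.all(np.abs(out.values) == 0)

    def test_magnitude_and_phase_hand_example(self):
        spg = stft_frames(_rec(np.zeros(48)))
        v = np.zeros((1, spg.n_frames, spg.spec.n_bins), dtype=complex)
        v[0, 0, 7] = 5.0 * np.exp(1j * np.pi / 4)
        spg.values = v
        noise = NoiseProfile(np.full((1, spg.spec.n_bins), 2.0), 1)
        out = spectral_subtract(spg, noise)
        assert abs(out.values[0, 0, 7]) == pytest.approx(3.0)
        assert np.angle(out.values[0, 0, 7]) == pytest.approx(np.pi / 4)

    def test_output_between_zero_and_input(self, noise_recording):
        spg = stft_frames(noise_recording)
        noise = estimate_noise_profile(spg, (0, 10))
        out = spectral_subtract(spg, noise)
        mag_in, mag_out = np.abs(spg.values), np.abs(out.values)
        assert np.all(mag_out >= 0)
        assert np.all(mag_out <= mag_in + 1e-12)

    def test_shape_mismatch_raises(self, noise_recording):
        spg = stft_frames(noise_recording)
        with pytest.raises(ValueError):
            spectral_subtract(spg, NoiseProfile(np.ones((1, 3)), 1))


class TestBandpassReconstruct:
    def _tone(self, f0, n=4096):
        t = np.arange(n) / 512.0
        return np.sin(2 * np.pi * f0 * t)

    def _rms_ratio(self, f0):
        x = self._tone(f0)
        out = bandpass_reconstruct(stft_frames(_rec(x)), BandSpec()).samples[0]
        i = slice(200, len(out) - 200)
        return np.sqrt(np.mean(out[i] ** 2)) / np.sqrt(np.mean(x[i] ** 2))

    def test_pass_band_tone_preserved(self):
        assert abs(self._rms_ratio(120.0) - 1.0) < 0.10

    def test_stop_band_tone_suppressed(self):
        # the 24-sample window's leakage bounds achievable rejection
        assert self._rms_ratio(50.0) < 0.05
        assert self._rms_ratio(220.0) < 0.10

    def test_zero_in_zero_out(self):
        out = bandpass_reconstruct(stft_frames(_rec(np.zeros(512))), BandSpec())
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-15)

    def test_near_idempotent(self, rng):
        x = rng.standard_normal((2, 2048))
        o1 = bandpass_reconstruct(stft_frames(EEGRecording(x, 512.0)), BandSpec())
        o2 = bandpass_reconstruct(stft_frames(o1), BandSpec())
        n = o2.n_samples
        i = slice(100, n - 100)
        rel = np.sqrt(np.mean((o2.samples[:, i] - o1.samples[:, :n][:, i]) ** 2))
        rel /= np.sqrt(np.mean(o1.samples[:, i] ** 2))
        # re-windowing leaks in-band energy out of the brick-wall mask, so
        # a second pass removes a further slice; it stays well under 20%
        assert rel < 0.2

    def test_band_outside_nyquist_raises(self, noise_recording):
        spg = stft_frames(noise_recording)
        with pytest.raises(ValueError):
            bandpass_reconstruct(spg, BandSpec(400.0, 500.0))

    def test_band_spec_validation(self):
        with pytest.raises(ValueError):
            BandSpec(180.0, 80.0)


class TestFullChain:
    def test_chain_raises_band_limited_snr(self, rng):
        # planted 120 Hz component + white noise; the chain should
        # improve the in-band signal-to-background ratio
        fs = 512.0
        n = 1536
        t = np.arange(n) / fs
        signal = np.zeros(n)
        signal[512:1024] = np.sin(2 * np.pi * 120.0 * t[512:1024]) * 2.0
        noise = rng.standard_normal((3, n))
        rec = EEGRecording(signal + noise, fs, ("C3", "C4", "Cz"))
        clean = preprocess(rec, (0, 20))
        m = min(clean.n_samples, n)

        def snr(x):
            sig = x[:, 512:1024]
            bg = x[:, 100:500]
            return np.mean(sig**2) / np.mean(bg**2)

        assert snr(clean.samples[:, :m]) > snr(rec.samples[:, :m])
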