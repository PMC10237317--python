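"""Denoising chain for imagined-speech EEG.

Four stages, applied per channel:

1. blockwise DC-bias removal (mean over 100 ms blocks subtracted);
2. short-time spectra — 24-sample (~48 ms at 512 Hz) Hann windows hopped
   every 12 samples, zero-padded to a 128-point FFT so the bin spacing is
   ``fs / 128`` (4 Hz at 512 Hz);
3. magnitude spectral subtraction of a mean noise spectrum estimated
   from the noise-only lead-in before imagery starts (Boll-style: the
   rectified magnitude keeps the original phase);
4. high-gamma band-pass (80-180 Hz) applied on the spectrum, followed by
   inverse-FFT overlap-add reconstruction of the time waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import hann

from .eeg_io import EEGRecording


@dataclass(frozen=True)
class FrameSpec:
    """Short-time analysis grid.

    48 ms at 512 Hz is 24.576 samples; the window is fixed at 24 samples
    so that the zero pad is exactly 128 - 24 = 104 points.  The ~24 ms
    hop truncates to 12 samples, giving exact 50% overlap (needed for
    constant-overlap-add reconstruction).
    """

    window_len: int = 24
    hop: int = 12
    n_fft: int = 128
    fs: float = 512.0

    def __post_init__(self) -> None:
        if self.window_len > self.n_fft:
            raise ValueError("window_len must be <= n_fft")
        if self.hop < 1:
            raise ValueError("hop must be >= 1")

    @property
    def zero_pad(self) -> int:
        return self.n_fft - self.window_len

    @property
    def n_bins(self) -> int:
        return self.n_fft // 2 + 1

    @property
    def freq_resolution(self) -> float:
        return self.fs / self.n_fft

    def bin_freqs(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.freq_resolution

    def n_frames(self, n_samples: int) -> int:
        if n_samples < self.window_len:
            raise ValueError("recording shorter than one analysis window")
        return (n_samples - self.window_len) // self.hop + 1

    def window(self) -> np.ndarray:
        # periodic Hann: overlapped copies at 50% hop sum to a constant
        return hann(self.window_len, sym=False)


@dataclass
class ComplexSpectrogram:
    """Complex short-time spectra, ``values[ch, frame, bin]``."""

    values: np.ndarray
    frame_onsets: np.ndarray
    spec: FrameSpec

    def __post_init__(self) -> None:
        if self.values.shape[-1] != self.spec.n_bins:
            raise ValueError("bin count does not match spec.n_fft")
        d = np.diff(self.frame_onsets)
        if d.size and not np.all(d == self.spec.hop):
            raise ValueError("frame onsets must advance by hop")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def magnitudes(self) -> np.ndarray:
        return np.abs(self.values)


@dataclass
class NoiseProfile:
    """Mean noise magnitude spectrum per channel, from the noise lead-in."""

    mean_magnitude: np.ndarray
    n_frames_used: int

    def __post_init__(self) -> None:
        if self.n_frames_used < 1:
            raise ValueError("noise profile needs at least one frame")
        if np.any(self.mean_magnitude < 0):
            raise ValueError("noise magnitudes must be non-negative")


@dataclass(frozen=True)
class BandSpec:
    """Analysis pass band, default the high-gamma 80-180 Hz range."""

    low: float = 80.0
    high: float = 180.0

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError("need 0 < low < high")

    def bin_mask(self, spec: FrameSpec) -> np.ndarray:
        """Boolean mask of bins whose centre frequency lies in [low, high]."""
        f = spec.bin_freqs()
        return (f >= self.low) & (f <= self.high)

    def bin_range(self, spec: FrameSpec) -> tuple[int, int]:
        """(first, last+1) bin index of the pass band."""
        idx = np.nonzero(self.bin_mask(spec))[0]
        return int(idx[0]), int(idx[-1]) + 1


def remove_dc_bias(rec: EEGRecording, block_ms: float = 100.0) -> EEGRecording:
    """Subtract the mean of each ``block_ms`` block from its samples.

    The final partial block uses its own mean, so every block of the
    output has zero mean.
    """
    if block_ms <= 0:
        raise ValueError("block_ms must be positive")
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    block = int(round(block_ms * rec.fs / 1000.0))
    block = max(block, 1)
    x = rec.samples.copy()
    for start in range(0, x.shape[1], block):
        seg = x[:, start : start + block]
        seg -= seg.mean(axis=1, keepdims=True)
    return EEGRecording(
        x, rec.fs, rec.channel_names, rec.subject_id, list(rec.annotations)
    )


def stft_frames(rec: EEGRecording, spec: FrameSpec | None = None) -> ComplexSpectrogram:
    """Hann-windowed, zero-padded short-time FFT on the analysis grid."""
    spec = spec or FrameSpec(fs=rec.fs)
    n_frames = spec.n_frames(rec.n_samples)
    onsets = np.arange(n_frames) * spec.hop
    idx = onsets[:, None] + np.arange(spec.window_len)[None, :]
    frames = rec.samples[:, idx] * spec.window()  # [ch, frame, window_len]
    values = np.fft.rfft(frames, n=spec.n_fft, axis=-1)
    return ComplexSpectrogram(values, onsets, spec)


def estimate_noise_profile(
    spg: ComplexSpectrogram, noise_frames: range | slice | tuple[int, int]
) -> NoiseProfile:
    """Mean magnitude spectrum over a frame range of the noise lead-in."""
    if isinstance(noise_frames, tuple):
        noise_frames = range(*noise_frames)
    if isinstance(noise_frames, slice):
        noise_frames = range(*noise_frames.indices(spg.n_frames))
    frames = list(noise_frames)
    if not frames:
        raise ValueError("empty noise frame range")
    if frames[0] < 0 or frames[-1] >= spg.n_frames:
        raise ValueError("noise frame range outside spectrogram")
    mags = np.abs(spg.values[:, frames, :])
    return NoiseProfile(mags.mean(axis=1), len(frames))


def spectral_subtract(
    spg: ComplexSpectrogram, noise: NoiseProfile, floor: float = 0.0
) -> ComplexSpectrogram:
    """Magnitude spectral subtraction with rectification, phase preserved.

    Output magnitude is ``max(|X| - N, floor * N)`` per bin; ``floor``
    (beta) defaults to 0, i.e. plain half-wave rectification.
    """
    if noise.mean_magnitude.shape != (spg.n_channels, spg.spec.n_bins):
        raise ValueError("noise profile shape does not match spectrogram")
    mag = np.abs(spg.values)
    nbar = noise.mean_magnitude[:, None, :]
    new_mag = np.maximum(mag - nbar, floor * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        phase = np.where(mag > 0, spg.values / np.where(mag > 0, mag, 1.0), 0.0)
    return ComplexSpectrogram(new_mag * phase, spg.frame_onsets, spg.spec)


def band_mask_spectrogram(
    spg: ComplexSpectrogram, band: BandSpec
) -> ComplexSpectrogram:
    """Zero every bin whose centre frequency falls outside the band."""
    if band.high > spg.spec.fs / 2:
        raise ValueError("band exceeds Nyquist frequency")
    mask = band.bin_mask(spg.spec)
    return ComplexSpectrogram(spg.values * mask, spg.frame_onsets, spg.spec)


def bandpass_reconstruct(
    spg: ComplexSpectrogram,
    band: BandSpec,
    channel_names: tuple[str, ...] | None = None,
) -> EEGRecording:
    """Band-limit the spectrum and rebuild the time waveform by overlap-add.

    Out-of-band bins are zeroed (edges inclusive), conjugate symmetry is
    implicit in the inverse real FFT, and frames are overlap-added on
    the analysis grid.  With a periodic Hann window at 50% overlap the
    window sum is constant, so in-band content is reconstructed exactly
    on interior samples.  The selectivity of the per-frame brick-wall
    mask is limited by the 24-sample window's spectral leakage.
    """
    masked = band_mask_spectrogram(spg, band)
    spec = spg.spec
    n_out = int(spg.frame_onsets[-1]) + spec.window_len
    frames = np.fft.irfft(masked.values, n=spec.n_fft, axis=-1)
    out = np.zeros((spg.n_channels, n_out))
    wsum = np.zeros(n_out)
    w = spec.window()
    for i, onset in enumerate(spg.frame_onsets):
        onset = int(onset)
        take = min(spec.n_fft, n_out - onset)
        out[:, onset : onset + take] += frames[:, i, :take]
        wsum[onset : onset + spec.window_len] += w
    # normalise by the window overlap sum where it is established
    ok = wsum > 1e-6
    out[:, ok] /= wsum[ok]
    names = channel_names or tuple(f"ch{i}" for i in range(spg.n_channels))
    return EEGRecording(out, spec.fs, names)


@dataclass(frozen=True)
class PreprocessConfig:
    block_ms: float = 100.0
    frame: FrameSpec = field(default_factory=FrameSpec)
    band: BandSpec = field(default_factory=BandSpec)
    ss_floor: float = 0.0


def preprocess(
    rec: EEGRecording,
    noise_frames: tuple[int, int],
    cfg: PreprocessConfig | None = None,
) -> EEGRecording:
    """Full chain: DC removal, STFT, spectral subtraction, band-pass + OLA."""
    cfg = cfg or PreprocessConfig(frame=FrameSpec(fs=rec.fs))
    rec = remove_dc_bias(rec, cfg.block_ms)
    spg = stft_frames(rec, cfg.frame)
    noise = estimate_noise_profile(spg, noise_frames)
    spg = spectral_subtract(spg, noise, cfg.ss_floor)
    out = bandpass_reconstruct(spg, cfg.band, tuple(rec.channel_names))
    return EEGRecording(
        out.samples, rec.fs, rec.channel_names, rec.subject_id, list(rec.annotations)
    )
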