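"""Linear predictive analysis (LPA) of band-limited EEG frames.

EEG carries no glottal pulse train, so the signal model is white-noise
excitation through an all-pole filter; the filter's magnitude response
``L(k) = 1 / |F{1, a1, ..., ap, 0, ...}|`` is taken as the carrier of
linguistic information.  Coefficients come from the biased
autocorrelation via the Levinson-Durbin recursion (order 8 by default),
and the smooth all-pole spectrum is reduced to a sparse *line spectrum*
of local maxima and shoulder inflection points found from discrete
first and second differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .eeg_io import EEGRecording
from .preprocess import BandSpec, FrameSpec

DEFAULT_ORDER = 8


@dataclass
class LPAModel:
    """Prediction coefficients ``(a0 ... ap)`` with ``a0 = 1``."""

    coeffs: np.ndarray
    residual_energy: float

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs[0] != 1.0:
            raise ValueError("a0 must be 1")
        if self.residual_energy < 0:
            raise ValueError("residual energy must be >= 0")

    @property
    def order(self) -> int:
        return len(self.coeffs) - 1


@dataclass(frozen=True)
class LagWindowSpec:
    """Optional taper on the autocorrelation sequence.

    The default is no lag window: an untapered autocorrelation keeps the
    all-pole peaks sharp, which suits line-spectrum conversion.
    """

    kind: str = "none"  # none | gaussian
    width: float = 8.0  # lags (standard deviation of the gaussian)

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian"):
            raise ValueError(f"unknown lag window kind {self.kind!r}")
        if self.kind != "none" and self.width < 1:
            raise ValueError("width must be >= 1 lag")


class LineKind(str, Enum):
    LOCAL_MAX = "local_max"
    INFLECTION = "inflection"


@dataclass(frozen=True)
class Line:
    bin: int
    freq: float
    amplitude: float
    kind: LineKind


@dataclass
class LineSpectrum:
    """Sparse rendering of an LPA spectrum: peak and shoulder lines."""

    lines: tuple[Line, ...]

    def __post_init__(self) -> None:
        bins = [l.bin for l in self.lines]
        if bins != sorted(set(bins)):
            raise ValueError("line bins must be strictly increasing")
        if any(l.amplitude <= 0 for l in self.lines):
            raise ValueError("line amplitudes must be positive")

    def bins(self) -> np.ndarray:
        return np.array([l.bin for l in self.lines], dtype=int)

    def dense(self, n_bins: int, offset: int = 0) -> np.ndarray:
        """Render amplitudes onto a dense bin grid (zeros off-line)."""
        v = np.zeros(n_bins)
        for l in self.lines:
            j = l.bin - offset
            if 0 <= j < n_bins:
                v[j] = l.amplitude
        return v


def autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased autocorrelation ``r(tau) = sum_n x(n) x(n+tau)``, lags 0..max_lag.

    The biased estimator keeps the Toeplitz system positive semidefinite,
    which the Levinson-Durbin recursion requires.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be 1-D")
    if max_lag >= len(x):
        raise ValueError("max_lag must be < len(x)")
    return np.array([x[: len(x) - t] @ x[t:] for t in range(max_lag + 1)])


def autocorrelation_batch(frames: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased autocorrelation along the last axis, lags 0..max_lag."""
    n = frames.shape[-1]
    if max_lag >= n:
        raise ValueError("max_lag must be < frame length")
    out = np.empty(frames.shape[:-1] + (max_lag + 1,))
    for t in range(max_lag + 1):
        out[..., t] = np.sum(frames[..., : n - t] * frames[..., t:], axis=-1)
    return out


def apply_lag_window(r: np.ndarray, spec: LagWindowSpec) -> np.ndarray:
    """Multiply the autocorrelation by the lag window (identity for none)."""
    r = np.asarray(r, dtype=float)
    if spec.kind == "none":
        return r.copy()
    lags = np.arange(r.shape[-1])
    w = np.exp(-0.5 * (lags / spec.width) ** 2)
    return r * w


def levinson_durbin(r: Sequence[float] | np.ndarray, p: int) -> LPAModel:
    """Fit order-``p`` prediction coefficients from autocorrelations.

    Solves the Toeplitz normal equations by the Levinson-Durbin
    recursion; the returned residual energy is the final prediction
    error of the recursion.
    """
    r = np.asarray(r, dtype=float)
    if len(r) < p + 1:
        raise ValueError("need r(0..p)")
    if r[0] <= 0:
        raise ValueError("r(0) must be positive")
    a, e = _levinson_batch(r[None, : p + 1])
    if not np.isfinite(e[0]) or e[0] < 0:
        raise np.linalg.LinAlgError("singular normal equations (non-positive error)")
    return LPAModel(a[0], float(e[0]))


def _levinson_batch(r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Levinson-Durbin over a batch: r is [batch, p+1] -> (a [batch, p+1], e [batch])."""
    batch, m = r.shape
    p = m - 1
    a = np.zeros((batch, p + 1))
    a[:, 0] = 1.0
    e = r[:, 0].astype(float).copy()
    for i in range(1, p + 1):
        acc = np.einsum("bj,bj->b", a[:, :i], r[:, i:0:-1])
        with np.errstate(divide="ignore", invalid="ignore"):
            k = np.where(e > 0, -acc / np.where(e > 0, e, 1.0), 0.0)
        a[:, 1 : i + 1] = a[:, 1 : i + 1] + k[:, None] * a[:, i - 1 :: -1][:, : i]
        e = e * (1.0 - k**2)
    return a, e


def levinson_batch(r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised recursion over leading axes; r is [..., p+1]."""
    lead = r.shape[:-1]
    a, e = _levinson_batch(r.reshape(-1, r.shape[-1]))
    return a.reshape(lead + (r.shape[-1],)), e.reshape(lead)


def lpa_spectrum(model: LPAModel, n_fft: int = 128) -> np.ndarray:
    """All-pole magnitude spectrum ``1/|F{a}|`` on bins 0..n_fft/2."""
    if n_fft < model.order + 1:
        raise ValueError("n_fft must be >= p + 1")
    denom = np.abs(np.fft.rfft(model.coeffs, n=n_fft))
    if np.any(denom == 0):
        raise ZeroDivisionError("pole on the unit circle: |F{a}| vanishes at a bin")
    return 1.0 / denom


def lpa_spectrum_batch(coeffs: np.ndarray, n_fft: int = 128) -> np.ndarray:
    """``1/|F{a}|`` along the last axis for a coefficient batch."""
    denom = np.abs(np.fft.rfft(coeffs, n=n_fft, axis=-1))
    return 1.0 / np.maximum(denom, 1e-300)


def extract_line_spectrum(
    spectrum: np.ndarray, freq_resolution: float
) -> LineSpectrum:
    """Reduce a smooth spectrum to local-maximum and shoulder-inflection lines.

    A ``local_max`` line sits at every bin where the first difference
    changes sign + to - (plateau ties resolve to the lowest bin).  An
    ``inflection`` line marks a shoulder: a - to + sign change of the
    second difference where the first difference keeps constant sign, so
    peak flanks are not duplicated.
    """
    s = np.asarray(spectrum, dtype=float)
    if len(s) < 3:
        raise ValueError("spectrum must have at least 3 bins")
    d1 = np.diff(s)
    sign1 = np.sign(d1)
    lines: list[Line] = []
    # local maxima: last positive slope before a negative one
    i = 0
    n = len(s)
    prev_sign = 0
    for b in range(1, n - 1):
        left, right = sign1[b - 1], sign1[b]
        if left > 0 and right < 0:
            lines.append(Line(b, b * freq_resolution, s[b], LineKind.LOCAL_MAX))
        elif left > 0 and right == 0:
            # plateau begins: lowest bin of the plateau takes the line
            j = b
            while j < n - 1 and sign1[j] == 0:
                j += 1
            if j < n - 1 and sign1[j] < 0:
                lines.append(Line(b, b * freq_resolution, s[b], LineKind.LOCAL_MAX))
    # shoulder inflections: second-difference - to + with monotone slope
    d2 = np.diff(s, 2)
    taken = {l.bin for l in lines}
    for b in range(1, len(d2)):
        if d2[b - 1] < 0 <= d2[b]:
            k = b + 1  # bin index of the d2[b] sample's centre
            if k in taken or not 0 < k < n - 1:
                continue
            if sign1[k - 1] != 0 and sign1[k - 1] == sign1[k] and s[k] > 0:
                lines.append(Line(k, k * freq_resolution, s[k], LineKind.INFLECTION))
                taken.add(k)
    lines.sort(key=lambda l: l.bin)
    return LineSpectrum(tuple(lines))


@dataclass(frozen=True)
class LPAConfig:
    order: int = DEFAULT_ORDER
    lag_window: LagWindowSpec = LagWindowSpec()
    per_chunk: bool = False  # concatenate a chunk's frames before fitting


def analyze_frames(
    rec: EEGRecording,
    spec: FrameSpec | None = None,
    cfg: LPAConfig | None = None,
    apply_gain: bool = True,
) -> np.ndarray:
    """All-pole spectra of every (channel, frame): returns [ch, frame, n_bins].

    Frames are cut on the same grid as the short-time analysis (no
    window — autocorrelation over the raw 24-sample frame).  With
    ``apply_gain`` each spectrum is scaled by the square root of its
    prediction-error energy (the AR model's excitation gain), so frame
    amplitudes reflect signal power rather than spectral shape alone —
    pooling across electrodes then favours electrodes that carry signal.
    """
    spec = spec or FrameSpec(fs=rec.fs)
    cfg = cfg or LPAConfig()
    n_frames = spec.n_frames(rec.n_samples)
    onsets = np.arange(n_frames) * spec.hop
    idx = onsets[:, None] + np.arange(spec.window_len)[None, :]
    frames = rec.samples[:, idx]  # [ch, frame, window_len]
    r = autocorrelation_batch(frames, cfg.order)
    if cfg.lag_window.kind != "none":
        r = apply_lag_window(r, cfg.lag_window)
    # guard silent frames: r(0)=0 would make the recursion divide by zero
    r[..., 0] = np.maximum(r[..., 0], 1e-12)
    a, e = levinson_batch(r)
    s = lpa_spectrum_batch(a, spec.n_fft)
    if apply_gain:
        s = s * np.sqrt(np.maximum(e, 0.0))[..., None]
    return s


def line_spectra_tensor(
    spectra: np.ndarray, band: BandSpec, spec: FrameSpec
) -> np.ndarray:
    """Dense line-spectrum rendering restricted to the pass band.

    ``spectra`` is [..., n_bins]; the result has the same leading shape
    over the band's bins, holding the spectrum value at local-maximum and
    shoulder-inflection bins and zero elsewhere.  Vectorised equivalent
    of :func:`extract_line_spectrum` + :meth:`LineSpectrum.dense`.
    """
    s = np.asarray(spectra, dtype=float)
    d1 = np.diff(s, axis=-1)
    sg = np.sign(d1)
    n = s.shape[-1]
    is_line = np.zeros(s.shape, dtype=bool)
    # strict local maxima (plateaus are measure-zero for all-pole spectra)
    is_line[..., 1:-1] = (sg[..., :-1] > 0) & (sg[..., 1:] < 0)
    d2 = np.diff(s, 2, axis=-1)
    shoulder = np.zeros(s.shape, dtype=bool)
    shoulder[..., 2:-1] = (
        (d2[..., :-1] < 0)
        & (d2[..., 1:] >= 0)
        & (sg[..., 1:-1] != 0)
        & (sg[..., 1:-1] == sg[..., 2:])
    )
    is_line |= shoulder & ~is_line
    lo, hi = band.bin_range(spec)
    out = np.where(is_line, s, 0.0)[..., lo:hi]
    return out


def spectrum_tensor(
    spectra: np.ndarray, band: BandSpec, spec: FrameSpec
) -> np.ndarray:
    """Full all-pole spectra restricted to the pass-band bins."""
    lo, hi = band.bin_range(spec)
    return np.asarray(spectra, dtype=float)[..., lo:hi]
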