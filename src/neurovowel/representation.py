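"""Vowel reference vectors and the P1-P2 chart.

A vowel's eigen space is condensed into a single reference spectrum

    G(v) = [ sum_m  (lambda_m / lambda_1) psi(v, m)^2 ]^(1/2)

an eigenvalue-weighted root-sum-square of the eigenvectors, with the
leading component entering at weight exactly 1.  G(v) shows two
prominent peaks (P1 < P2) in the upper part of the analysis band,
playing the role that formants F1/F2 play for spoken vowels; plotting
each vowel at its (P1, P2) point gives the chart on which the five
vowels line up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import BandSpec
from .vowel_search import EigenSpace


@dataclass
class ReferenceVector:
    vowel: str
    values: np.ndarray  # non-negative, over band bins

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("reference vector must be non-negative")


@dataclass
class PeakPair:
    """The two dominant peaks of G(v), ordered p1 < p2 (Hz)."""

    p1: float
    p2: float
    p1_amp: float
    p2_amp: float

    def __post_init__(self) -> None:
        if not self.p1 < self.p2:
            raise ValueError("need p1 < p2")


def reference_vector(space: EigenSpace) -> ReferenceVector:
    """Accumulated spectrum of an eigen space, weights lambda_m / lambda_1."""
    lam = space.eigenvalues
    if lam[0] <= 0:
        raise ValueError("leading eigenvalue must be positive")
    w = lam / lam[0]
    g = np.sqrt(np.sum(w[:, None] * space.basis**2, axis=0))
    return ReferenceVector(space.vowel, g)


def _local_maxima(values: np.ndarray) -> list[int]:
    """Strict discrete-difference peaks; plateau ties go to the lowest bin."""
    out = []
    d = np.sign(np.diff(values))
    n = len(values)
    for b in range(1, n - 1):
        if d[b - 1] > 0 and d[b] < 0:
            out.append(b)
        elif d[b - 1] > 0 and d[b] == 0:
            j = b
            while j < n - 1 and d[j] == 0:
                j += 1
            if j < n - 1 and d[j] < 0:
                out.append(b)
    return out


def _curvature_maxima(values: np.ndarray) -> list[tuple[float, int]]:
    """(score, bin) of local maxima of the negative second difference.

    Convex bumps riding a broad envelope — the typical shape of G when
    per-frame spectral scatter has smeared the underlying peaks — show
    up far more sharply in curvature than in raw amplitude.
    """
    c = -(values[2:] - 2 * values[1:-1] + values[:-2])  # centred at i+1
    out = []
    for i in range(1, len(c) - 1):
        if c[i] > 0 and c[i] >= c[i - 1] and c[i] > c[i + 1]:
            out.append((float(c[i]), i + 1))
    return out


def extract_p1_p2(
    g: ReferenceVector,
    min_freq: float = 120.0,
    band: BandSpec | None = None,
    freq_resolution: float = 4.0,
    bin_offset: int = 0,
    method: str = "curvature",
) -> PeakPair:
    """The two dominant peaks of G at or above ``min_freq``.

    ``min_freq`` operationalises the "upper frequency range": peaks
    below it are ignored.  ``bin_offset`` maps vector indices to
    absolute FFT bins (for band-restricted vectors).  ``method``
    ranks candidate peaks by negative-second-difference curvature
    (default; robust when the two peaks ride a broad common envelope)
    or by raw ``"amplitude"`` of discrete-difference local maxima.
    Returned with p1 < p2; score ties resolve to the lower frequency.
    """
    band = band or BandSpec()
    freqs = (bin_offset + np.arange(len(g.values))) * freq_resolution
    if method == "curvature":
        scored = _curvature_maxima(g.values)
    elif method == "amplitude":
        scored = [(float(g.values[b]), b) for b in _local_maxima(g.values)]
    else:
        raise ValueError(f"unknown method {method!r}")
    cand = [
        (s, b)
        for s, b in scored
        if freqs[b] >= min_freq and band.low <= freqs[b] <= band.high
    ]
    if len(cand) < 2:
        raise ValueError(
            f"found {len(cand)} qualifying maxima for /{g.vowel}/, need 2"
        )
    cand.sort(key=lambda sb: (-sb[0], freqs[sb[1]]))
    top = sorted((b for _, b in cand[:2]))
    return PeakPair(
        freqs[top[0]], freqs[top[1]], g.values[top[0]], g.values[top[1]]
    )


def build_chart(
    pairs: Mapping[str, Sequence[tuple[str, PeakPair]]]
) -> pd.DataFrame:
    """P1-P2 chart table: per-subject points plus unweighted per-vowel means.

    ``pairs`` maps vowel -> list of (subject_id, PeakPair).  Rows with
    ``is_mean`` set hold the per-vowel arithmetic means.
    """
    rows = []
    for vowel, entries in pairs.items():
        if not entries:
            raise ValueError(f"vowel {vowel!r} has no subjects")
        for subject, p in entries:
            rows.append((vowel, subject, p.p1, p.p2, False))
        p1s = [p.p1 for _, p in entries]
        p2s = [p.p2 for _, p in entries]
        rows.append((vowel, "MEAN", float(np.mean(p1s)), float(np.mean(p2s)), True))
    if not rows:
        raise ValueError("no peak pairs supplied")
    return pd.DataFrame(
        rows, columns=["vowel", "subject", "p1_hz", "p2_hz", "is_mean"]
    )


def chart_line_fit(chart: pd.DataFrame) -> tuple[float, float, float]:
    """Least-squares line p2 = a*p1 + b through the vowel means.

    Returns (slope, intercept, residual RMS in Hz) — the five vowels'
    mean points lie roughly on a line in the P1-P2 plane.
    """
    means = chart[chart["is_mean"]]
    x = means["p1_hz"].to_numpy()
    y = means["p2_hz"].to_numpy()
    a, b = np.polyfit(x, y, 1)
    resid = y - (a * x + b)
    return float(a), float(b), float(np.sqrt(np.mean(resid**2)))
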