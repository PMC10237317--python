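"""Electrode pooling and monosyllable chunk proposal.

Imagined speech has no audio reference track, so syllables must be
found in the EEG itself.  Pooling the line spectra of all electrodes
makes chunks of discrete CV syllables visible: vowels stay spectrally
stable across several consecutive frames, so a chunk shows up as a run
of frames with near-identical pooled line sets.  True chunks last 7-9
analysis frames; spurious "pseudo-syllables" resembling real ones
appear alongside them, which is why downstream processing re-selects
frames by subspace similarity rather than trusting every run.

Published analyses of this kind label chunks by hand; the proposer here
is a reproducible stand-in so the pipeline can run unattended, and hand
labels remain loadable through :mod:`neurovowel.eeg_io`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lpa import Line, LineKind, LineSpectrum


@dataclass
class PooledLineSpectrogram:
    """Per-frame line spectra after union-with-max pooling over electrodes."""

    frames: list[LineSpectrum]
    n_electrodes_pooled: int

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class ChunkCandidate:
    """A proposed monosyllable chunk: a stable run of pooled frames."""

    start_frame: int
    n_frames: int
    stability_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.stability_score <= 1.0 + 1e-12:
            raise ValueError("stability_score must lie in [0, 1]")


def pool_line_spectra(
    per_channel: list[list[LineSpectrum]],
) -> PooledLineSpectrogram:
    """Union-with-max pooling of line spectra across electrodes.

    Per frame, the pooled line set is the union of the channels' line
    bins; at each bin the amplitude is the maximum over channels and the
    kind is the maximal contributor's.
    """
    if not per_channel:
        raise ValueError("no channels to pool")
    n_frames = len(per_channel[0])
    if any(len(ch) != n_frames for ch in per_channel):
        raise ValueError("channels disagree on frame count")
    pooled: list[LineSpectrum] = []
    for f in range(n_frames):
        best: dict[int, Line] = {}
        for ch in per_channel:
            for line in ch[f].lines:
                cur = best.get(line.bin)
                if cur is None or line.amplitude > cur.amplitude:
                    best[line.bin] = line
        pooled.append(LineSpectrum(tuple(best[b] for b in sorted(best))))
    return PooledLineSpectrogram(pooled, len(per_channel))


def pool_dense(tensors: np.ndarray) -> np.ndarray:
    """Max-pool dense line tensors over the channel axis: [ch, frame, bin] -> [frame, bin]."""
    return np.max(tensors, axis=0)


def dense_to_line_spectra(
    dense: np.ndarray, bin_offset: int = 0, freq_resolution: float = 4.0
) -> list[LineSpectrum]:
    """Per-frame LineSpectrum objects from a dense [frame, bin] line tensor."""
    out = []
    for row in np.asarray(dense, dtype=float):
        nz = np.nonzero(row > 0)[0]
        out.append(
            LineSpectrum(
                tuple(
                    Line(
                        int(b) + bin_offset,
                        (int(b) + bin_offset) * freq_resolution,
                        float(row[b]),
                        LineKind.LOCAL_MAX,
                    )
                    for b in nz
                )
            )
        )
    return out


def _bin_similarity(a: np.ndarray, b: np.ndarray, tol: int = 1) -> float:
    """Jaccard similarity of two bin sets, matching within +/- tol bins."""
    if len(a) == 0 and len(b) == 0:
        return 1.0
    if len(a) == 0 or len(b) == 0:
        return 0.0
    hit_a = np.array([np.min(np.abs(b - x)) <= tol for x in a])
    hit_b = np.array([np.min(np.abs(a - x)) <= tol for x in b])
    inter = 0.5 * (hit_a.sum() + hit_b.sum())
    union = len(a) + len(b) - inter
    return float(inter / union)


def _top_bins(f: LineSpectrum, k: int | None) -> np.ndarray:
    if k is None or len(f.lines) <= k:
        return f.bins()
    order = sorted(f.lines, key=lambda l: -l.amplitude)[:k]
    return np.array(sorted(l.bin for l in order), dtype=int)


def frame_similarities(
    pooled: PooledLineSpectrogram, tol: int = 1, top_k: int | None = 4
) -> np.ndarray:
    """Adjacent-frame line-set similarity, length ``n_frames - 1``.

    With 21 electrodes pooled, the raw union can cover nearly every
    bin, so only the ``top_k`` strongest lines per frame enter the
    comparison (the dominant lines one would judge a chunk by).
    """
    bins = [_top_bins(f, top_k) for f in pooled.frames]
    return np.array(
        [_bin_similarity(bins[i], bins[i + 1], tol) for i in range(len(bins) - 1)]
    )


def propose_chunks(
    pooled: PooledLineSpectrogram,
    min_frames: int = 7,
    max_frames: int = 9,
    threshold: float = 0.5,
    tol: int = 1,
    top_k: int | None = 4,
    mode: str = "similarity",
    energy_factor: float = 1.3,
) -> list[ChunkCandidate]:
    """Propose chunks as maximal runs of spectrally stable frames.

    Two detection modes share the run bookkeeping:

    * ``"similarity"`` — a run is a maximal stretch of consecutive
      frames whose adjacent similarity (Jaccard over the ``top_k``
      strongest line bins, +/- ``tol`` bins) stays at or above
      ``threshold``.  Suits clean, low-electrode-count data.
    * ``"energy"`` — a run is a maximal stretch of frames whose total
      pooled line amplitude is at least ``energy_factor`` times the
      trial median; each candidate's onset is then refined to the
      placement (within +/-3 frames) maximising the energy captured by
      its window.  With many pooled electrodes the per-frame line
      *positions* scatter too much for the similarity gate, while an
      imagery chunk still stands out as sustained in-band power.

    Runs shorter than ``min_frames`` are dropped; longer ones are
    clipped to their first ``max_frames`` frames.  The stability score
    is always the mean adjacent-frame line similarity over the
    candidate.  Candidates are sorted by onset and never overlap.
    """
    if not 1 <= min_frames <= max_frames:
        raise ValueError("need 1 <= min_frames <= max_frames")
    if pooled.n_frames < 2:
        return []
    sims = frame_similarities(pooled, tol, top_k)
    energy = None
    if mode == "similarity":
        good = np.concatenate([sims >= threshold, [False]])
        # frame f is "good" if the edge (f, f+1) passes; runs span edges
        run_is_edges = True
    elif mode == "energy":
        energy = np.array(
            [sum(l.amplitude for l in f.lines) for f in pooled.frames]
        )
        med = np.median(energy)
        good = energy >= energy_factor * max(med, 1e-300)
        run_is_edges = False
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out: list[ChunkCandidate] = []
    i = 0
    n = len(good)
    while i < n:
        if not good[i]:
            i += 1
            continue
        j = i
        while j < n and good[j]:
            j += 1
        run_len = (j - i + 1) if run_is_edges else (j - i)
        # a run much longer than max_frames is several chunks back to
        # back (e.g. a distractor abutting a true chunk): split it into
        # consecutive candidates rather than keeping only its head
        s = i
        while run_len >= min_frames:
            take = min(run_len, max_frames)
            start = s
            if energy is not None:
                lo_s = max(0, s - 3)
                hi_s = min(len(energy) - take, s + 3)
                if hi_s >= lo_s:
                    sums = [
                        float(energy[t : t + take].sum())
                        for t in range(lo_s, hi_s + 1)
                    ]
                    start = lo_s + int(np.argmax(sums))
            score = float(np.mean(sims[start : start + take - 1]))
            out.append(ChunkCandidate(start, take, min(max(score, 0.0), 1.0)))
            s += take
            run_len -= take
        i = j
    # refinement may nudge neighbouring candidates into contact; keep order
    out.sort(key=lambda c: c.start_frame)
    pruned: list[ChunkCandidate] = []
    for c in out:
        if pruned and c.start_frame < pruned[-1].start_frame + pruned[-1].n_frames:
            continue
        pruned.append(c)
    return pruned
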