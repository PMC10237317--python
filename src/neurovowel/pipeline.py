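"""End-to-end pipeline: corpus -> denoised spectra -> line spectra ->
chunks -> eigen spaces -> reference vectors -> P1-P2 chart -> classifiers.

Per trial the chain is: DC removal, short-time spectra, spectral
subtraction of the lead-in noise profile, 80-180 Hz band-pass with
overlap-add reconstruction, all-pole analysis per (channel, frame), and
dense line-spectrum rendering over the pass-band bins.  Chunk tensors
are cut on the analysis-frame grid at labeled onsets; vowel labels come
either from hand labels / the synthetic manifest, or from the chunk
proposer matched against labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eeg_io import VOWELS, EEGRecording
from .labeling import ChunkCandidate
from .lpa import LPAConfig, analyze_frames, line_spectra_tensor, spectrum_tensor
from .preprocess import BandSpec, FrameSpec, PreprocessConfig, preprocess
from .representation import (
    PeakPair,
    ReferenceVector,
    build_chart,
    chart_line_fit,
    extract_p1_p2,
    reference_vector,
)
from .synthgen import SyntheticCorpus, noise_frame_range
from .vowel_search import SearchConfig, iterative_search


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end settings.

    ``sample_kind`` chooses the spectrum samples the vowel search and
    classifiers consume: the full all-pole spectrum over the pass-band
    bins (default — peak structure survives the bin grid), or the
    sparse line-spectrum rendering ("line").
    """

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    lpa: LPAConfig = field(default_factory=LPAConfig)
    search: SearchConfig = field(default_factory=SearchConfig)
    sample_kind: str = "lpa_spectrum"  # or "line"
    min_peak_freq: float | None = None  # None: admit peaks across the band

    def __post_init__(self) -> None:
        if self.sample_kind not in ("lpa_spectrum", "line"):
            raise ValueError(f"unknown sample_kind {self.sample_kind!r}")


def trial_feature_tensor(
    rec: EEGRecording,
    noise_frames: tuple[int, int],
    cfg: PipelineConfig | None = None,
) -> np.ndarray:
    """Preprocess one trial and return spectrum samples [ch, frame, band_bins]."""
    cfg = cfg or PipelineConfig()
    clean = preprocess(rec, noise_frames, cfg.preprocess)
    spectra = analyze_frames(clean, cfg.preprocess.frame, cfg.lpa)
    render = spectrum_tensor if cfg.sample_kind == "lpa_spectrum" else line_spectra_tensor
    return render(spectra, cfg.preprocess.band, cfg.preprocess.frame)


# older name, kept for the line rendering specifically
def trial_line_tensor(
    rec: EEGRecording,
    noise_frames: tuple[int, int],
    cfg: PipelineConfig | None = None,
) -> np.ndarray:
    cfg = cfg or PipelineConfig()
    clean = preprocess(rec, noise_frames, cfg.preprocess)
    spectra = analyze_frames(clean, cfg.preprocess.frame, cfg.lpa)
    return line_spectra_tensor(spectra, cfg.preprocess.band, cfg.preprocess.frame)


def cut_chunk(lines: np.ndarray, onset_frame: int, n_frames: int) -> np.ndarray:
    """Chunk tensor [ch, n_frames, band_bins] starting at an analysis frame."""
    if onset_frame < 0 or onset_frame + n_frames > lines.shape[1]:
        raise ValueError("chunk extends outside the trial's frame grid")
    return lines[:, onset_frame : onset_frame + n_frames, :]


@dataclass
class SubjectChunks:
    chunks: list[np.ndarray]
    vowels: list[str]


def corpus_chunks(
    corpus: SyntheticCorpus, cfg: PipelineConfig | None = None
) -> dict[str, SubjectChunks]:
    """Run preprocessing + line analysis and cut every true chunk, per subject."""
    cfg = cfg or PipelineConfig()
    nf = noise_frame_range(corpus.config)
    truth = corpus.true_chunks()
    out: dict[str, SubjectChunks] = {}
    for subject in corpus.subjects:
        rows = truth[truth["subject"] == subject]
        chunks, vowels = [], []
        for _, row in rows.iterrows():
            rec = corpus.recordings[subject][int(row["trial"])]
            feats = trial_feature_tensor(rec, nf, cfg)
            chunks.append(
                cut_chunk(feats, int(row["onset_frame"]), int(row["n_frames"]))
            )
            vowels.append(str(row["vowel"]))
        out[subject] = SubjectChunks(chunks, vowels)
    return out


def chunks_by_vowel(
    subject_chunks: dict[str, SubjectChunks], subjects: list[str] | None = None
) -> dict[str, list[np.ndarray]]:
    by_vowel: dict[str, list[np.ndarray]] = {v: [] for v in VOWELS}
    for s in subjects or sorted(subject_chunks):
        sc = subject_chunks[s]
        for c, v in zip(sc.chunks, sc.vowels):
            by_vowel[v].append(c)
    return by_vowel


def label_candidates(
    candidates: list[ChunkCandidate],
    manifest_rows: pd.DataFrame,
    max_onset_error: int = 1,
) -> list[tuple[ChunkCandidate, str]]:
    """Attach vowel labels to proposed chunks by onset match against labels.

    Stand-in for the hand-labeling step: a candidate within
    ``max_onset_error`` frames of a labeled true chunk takes its vowel.
    """
    out = []
    for cand in candidates:
        d = (manifest_rows["onset_frame"] - cand.start_frame).abs()
        if len(d) and d.min() <= max_onset_error:
            row = manifest_rows.loc[d.idxmin()]
            out.append((cand, str(row["vowel"])))
    return out


@dataclass
class RepresentationResult:
    references: dict[str, ReferenceVector]
    peaks: dict[str, PeakPair]
    chart: pd.DataFrame
    line_fit: tuple[float, float, float]  # slope, intercept, residual RMS (Hz)


def subject_peak_pairs(
    subject_chunks: dict[str, SubjectChunks], cfg: PipelineConfig | None = None
) -> RepresentationResult:
    """Per-subject eigen search, reference vectors, P1/P2 and the chart."""
    cfg = cfg or PipelineConfig()
    band = cfg.preprocess.band
    lo, _ = band.bin_range(cfg.preprocess.frame)
    dres = cfg.preprocess.frame.freq_resolution
    min_freq = cfg.min_peak_freq if cfg.min_peak_freq is not None else band.low
    pairs: dict[str, list[tuple[str, PeakPair]]] = {v: [] for v in VOWELS}
    refs: dict[str, ReferenceVector] = {}
    for subject in sorted(subject_chunks):
        by_vowel = chunks_by_vowel(subject_chunks, [subject])
        spaces, _ = iterative_search(by_vowel, cfg.search)
        for v, sp in spaces.items():
            g = reference_vector(sp)
            refs[v] = g  # keep the last subject's G for inspection
            try:
                pk = extract_p1_p2(
                    g, min_freq=min_freq, band=band,
                    freq_resolution=dres, bin_offset=lo,
                )
            except ValueError:
                # a subject whose G shows fewer than two peaks for this
                # vowel contributes no point, like an unreadable chart entry
                continue
            pairs[v].append((subject, pk))
    empty = [v for v, e in pairs.items() if not e]
    if empty:
        raise ValueError(f"no subject yielded a peak pair for vowels {empty}")
    chart = build_chart(pairs)
    means = {
        v: PeakPair(
            float(chart[(chart.vowel == v) & chart.is_mean]["p1_hz"].iloc[0]),
            float(chart[(chart.vowel == v) & chart.is_mean]["p2_hz"].iloc[0]),
            0.0, 0.0,
        )
        if not (chart[(chart.vowel == v) & chart.is_mean]).empty
        else None
        for v in VOWELS
    }
    peaks = {v: p for v, p in means.items() if p is not None}
    return RepresentationResult(refs, peaks, chart, chart_line_fit(chart))
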