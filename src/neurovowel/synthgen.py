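"""Synthetic imagined-speech EEG corpora with full ground truth.

The generator runs the encoding model forward: a white-noise excitation
W(k) is shaped by an all-pole "linguistic" filter whose conjugate pole
pairs sit at a vowel's two planted spectral peaks (P1, P2), then mixed
into 21 channels with random per-channel gains and buried in additive
background noise.  Each trial carries a noise-only lead-in (for noise
profile estimation), one true vowel chunk of 9 analysis frames at a
frame-aligned onset, and a Poisson number of lower-gain pseudo-syllable
distractor chunks.  A manifest records every chunk's subject, trial,
onset, vowel and pseudo flag, so decoding accuracy can be measured
against construction.

Deliberately *not* modelled: 1/f background spectra, volume conduction,
ocular/muscle artifacts, and any subject-specific spectral shift — the
corpus exercises the pipeline's signal path, not EEG biophysics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .eeg_io import MCN_21, VOWELS, CorpusProtocol, EEGRecording, load_protocol
from .preprocess import FrameSpec


@dataclass(frozen=True)
class VowelTemplate:
    """Planted spectral identity of one vowel: peaks P1 < P2 (Hz)."""

    vowel: str
    p1: float
    p2: float
    bandwidth: float = 8.0  # -3 dB bandwidth per pole pair, Hz
    gain: float = 1.0  # chunk RMS in microvolts

    def __post_init__(self) -> None:
        if not 80.0 <= self.p1 < self.p2 <= 180.0:
            raise ValueError("need 80 <= p1 < p2 <= 180 Hz")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")

    def ar_coeffs(self, fs: float) -> np.ndarray:
        """Order-4 all-pole coefficients with pole pairs at p1 and p2."""
        r = np.exp(-np.pi * self.bandwidth / fs)
        if r >= 1.0:
            raise ValueError("pole radius >= 1: unstable filter request")
        a = np.array([1.0])
        for f in (self.p1, self.p2):
            theta = 2 * np.pi * f / fs
            pair = np.array([1.0, -2 * r * np.cos(theta), r * r])
            a = np.convolve(a, pair)
        return a


def default_templates() -> tuple[VowelTemplate, ...]:
    """Five vowel templates with exactly colinear (P1, P2) points.

    P1 steps by 8 Hz (2 FFT bins at the 4 Hz grid) and P2 = P1 + 36 Hz,
    so the pairs lie on the unit-slope line, every peak falls on a bin
    centre of the default analysis grid, the pair separation stays
    resolvable by order-8 all-pole fits on 24-sample frames, and all
    peaks keep a >=16 Hz margin from the 80/180 Hz band edges that
    survives per-subject jitter.
    """
    p1s = (96.0, 104.0, 112.0, 120.0, 128.0)
    return tuple(
        VowelTemplate(v, p1, p1 + 36.0) for v, p1 in zip(VOWELS, p1s)
    )


@dataclass(frozen=True)
class SynthConfig:
    """Corpus-level generation settings.

    With ``chunks_per_vowel`` unset, per-vowel trial counts follow the
    protocol's repetition counts (50/50/65/60/60 -> 285 per subject).
    Each subject's vowel peaks are jittered by a zero-mean normal
    (``subject_peak_jitter_hz`` SD), emulating inter-subject spectral
    variability — the main obstacle to subject-independent decoding.
    """

    templates: tuple[VowelTemplate, ...] = field(default_factory=default_templates)
    fs: float = 512.0
    n_subjects: int = 5
    chunks_per_vowel: int | None = None
    chunk_frames: int = 9
    noise_sigma: float = 1.0
    subject_peak_jitter_hz: float = 1.5
    pseudo_rate: float = 1.0
    pseudo_gain_factor: float = 0.5
    noise_lead_in_ms: float = 500.0
    imagery_ms: float = 1000.0
    channel_gain_range: tuple[float, float] = (0.5, 1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if len({t.vowel for t in self.templates}) != len(self.templates):
            raise ValueError("duplicate vowels among templates")

    def template_for(self, vowel: str) -> VowelTemplate:
        for t in self.templates:
            if t.vowel == vowel:
                return t
        raise KeyError(vowel)

    def frame_spec(self) -> FrameSpec:
        return FrameSpec(fs=self.fs)

    def counts_per_vowel(self, protocol: CorpusProtocol | None = None) -> dict[str, int]:
        if self.chunks_per_vowel is not None:
            return {t.vowel: self.chunks_per_vowel for t in self.templates}
        protocol = protocol or load_protocol()
        return dict(protocol.repetitions_per_vowel)


def _jitter_template(
    t: VowelTemplate, cfg: SynthConfig, rng: np.random.Generator
) -> VowelTemplate:
    """A subject's personal variant of a vowel template."""
    if cfg.subject_peak_jitter_hz <= 0:
        return t
    j1, j2 = rng.normal(0.0, cfg.subject_peak_jitter_hz, size=2)
    p1 = float(np.clip(t.p1 + j1, 82.0, 168.0))
    p2 = float(np.clip(t.p2 + j2, p1 + 8.0, 178.0))
    return replace(t, p1=p1, p2=p2)


def chunk_length_samples(cfg: SynthConfig) -> int:
    spec = cfg.frame_spec()
    return spec.window_len + (cfg.chunk_frames - 1) * spec.hop


def synthesize_chunk(
    template: VowelTemplate, cfg: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """One vowel chunk: white noise through the template's all-pole filter.

    Length is ``chunk_frames`` analysis frames; the waveform is RMS-
    normalised to the template gain (all-zero when gain is 0).
    """
    n = chunk_length_samples(cfg)
    a = template.ar_coeffs(cfg.fs)
    # warm-up samples flush the filter transient
    w = rng.standard_normal(n + 256)
    x = lfilter([1.0], a, w)[256:]
    rms = np.sqrt(np.mean(x**2))
    if template.gain == 0 or rms == 0:
        return np.zeros(n)
    return x * (template.gain / rms)


def template_sample_vector(
    t: VowelTemplate,
    band=None,
    spec: FrameSpec | None = None,
    kind: str = "lpa_spectrum",
) -> np.ndarray:
    """The planted template rendered in the pipeline's sample space.

    The analytic all-pole spectrum of the template's filter on the FFT
    bin grid, restricted to the pass band — either the full spectrum or
    its line rendering — normalised to unit length.  This is the ground
    truth that recovered eigenvectors are compared against.
    """
    from .lpa import extract_line_spectrum
    from .preprocess import BandSpec

    band = band or BandSpec()
    spec = spec or FrameSpec()
    a = t.ar_coeffs(spec.fs)
    s = 1.0 / np.abs(np.fft.rfft(a, spec.n_fft))
    lo, hi = band.bin_range(spec)
    if kind == "lpa_spectrum":
        v = s[lo:hi]
    elif kind == "line":
        ls = extract_line_spectrum(s, spec.freq_resolution)
        v = np.zeros(hi - lo)
        for line in ls.lines:
            if line.kind.value == "local_max" and lo <= line.bin < hi:
                v[line.bin - lo] = line.amplitude
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return v / np.linalg.norm(v)


@dataclass
class SyntheticCorpus:
    """Generated recordings plus the ground-truth manifest."""

    config: SynthConfig
    recordings: dict[str, list[EEGRecording]]  # subject -> trials
    manifest: pd.DataFrame

    @property
    def subjects(self) -> list[str]:
        return sorted(self.recordings)

    def true_chunks(self) -> pd.DataFrame:
        return self.manifest[~self.manifest["is_pseudo"]].reset_index(drop=True)


def synthesize_corpus(
    cfg: SynthConfig, protocol: CorpusProtocol | None = None
) -> SyntheticCorpus:
    """Generate the full multi-subject corpus (bit-reproducible per seed)."""
    rng = np.random.default_rng(cfg.seed)
    spec = cfg.frame_spec()
    lead_in = int(round(cfg.noise_lead_in_ms * cfg.fs / 1000.0))
    imagery = int(round(cfg.imagery_ms * cfg.fs / 1000.0))
    n_total = lead_in + imagery
    clen = chunk_length_samples(cfg)
    counts = cfg.counts_per_vowel(protocol)
    # frame-aligned candidate onsets inside the imagery interval
    first_k = -(-lead_in // spec.hop)  # ceil: first full frame after lead-in
    last_k = (n_total - clen) // spec.hop
    if last_k < first_k:
        raise ValueError("imagery interval too short for one chunk")

    recordings: dict[str, list[EEGRecording]] = {}
    rows = []
    n_ch = len(MCN_21)
    for si in range(cfg.n_subjects):
        subject = f"S{si + 1:02d}"
        lo, hi = cfg.channel_gain_range
        ch_gain = rng.uniform(lo, hi, size=n_ch)
        subj_templates = {
            t.vowel: _jitter_template(t, cfg, rng) for t in cfg.templates
        }
        vowel_seq = [v for v in VOWELS for _ in range(counts.get(v, 0))]
        rng.shuffle(vowel_seq)
        trials = []
        for ti, vowel in enumerate(vowel_seq):
            x = rng.standard_normal((n_ch, n_total)) * cfg.noise_sigma
            onset_k = int(rng.integers(first_k, last_k + 1))
            onset = onset_k * spec.hop
            chunk = synthesize_chunk(subj_templates[vowel], cfg, rng)
            x[:, onset : onset + clen] += ch_gain[:, None] * chunk
            st = subj_templates[vowel]
            rows.append(
                (subject, ti, vowel, onset, onset_k, cfg.chunk_frames, False,
                 st.p1, st.p2)
            )
            # distractor pseudo-syllables, placed clear of the true chunk
            for _ in range(rng.poisson(cfg.pseudo_rate)):
                pv = VOWELS[int(rng.integers(len(VOWELS)))]
                pt = subj_templates[pv]
                pt = replace(pt, gain=pt.gain * cfg.pseudo_gain_factor)
                for _attempt in range(8):
                    pk = int(rng.integers(first_k, last_k + 1))
                    po = pk * spec.hop
                    if po + clen <= onset or po >= onset + clen:
                        pc = synthesize_chunk(pt, cfg, rng)
                        x[:, po : po + clen] += ch_gain[:, None] * pc
                        rows.append(
                            (subject, ti, pv, po, pk, cfg.chunk_frames, True,
                             pt.p1, pt.p2)
                        )
                        break
            trials.append(
                EEGRecording(x, cfg.fs, MCN_21, subject_id=subject)
            )
        recordings[subject] = trials
    manifest = pd.DataFrame(
        rows,
        columns=[
            "subject", "trial", "vowel",
            "onset_sample", "onset_frame", "n_frames", "is_pseudo",
            "subject_p1", "subject_p2",
        ],
    )
    return SyntheticCorpus(cfg, recordings, manifest)


def noise_frame_range(cfg: SynthConfig) -> tuple[int, int]:
    """Frames lying entirely inside the noise lead-in, as (start, stop)."""
    spec = cfg.frame_spec()
    lead_in = int(round(cfg.noise_lead_in_ms * cfg.fs / 1000.0))
    n = (lead_in - spec.window_len) // spec.hop + 1
    return 0, max(n, 1)


def save_corpus(corpus: SyntheticCorpus, out_dir: str | Path) -> None:
    """Write trials as HDF5 recordings plus a manifest TSV."""
    from .eeg_io import write_recording

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for subject, trials in corpus.recordings.items():
        for ti, rec in enumerate(trials):
            write_recording(rec, out / f"{subject}_trial{ti:04d}.h5")
    corpus.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)


def load_corpus(in_dir: str | Path, cfg: SynthConfig | None = None) -> SyntheticCorpus:
    """Read back a corpus written by :func:`save_corpus`.

    ``cfg`` supplies the generation settings when known; defaults are
    assumed otherwise (the manifest carries the ground truth needed by
    downstream stages either way).
    """
    from .eeg_io import read_recording

    src = Path(in_dir)
    manifest = pd.read_csv(src / "manifest.tsv", sep="\t")
    recordings: dict[str, list[EEGRecording]] = {}
    for path in sorted(src.glob("*_trial*.h5")):
        subject = path.name.split("_trial")[0]
        recordings.setdefault(subject, []).append(read_recording(path))
    if not recordings:
        raise FileNotFoundError(f"no trial recordings under {src}")
    return SyntheticCorpus(cfg or SynthConfig(), recordings, manifest)
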