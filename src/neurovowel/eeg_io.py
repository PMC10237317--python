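"""Recordings, protocol and label I/O.

Data model for multichannel scalp EEG together with the experiment
protocol (the 57-syllable inventory) and syllable label files.  Three
on-disk recording formats are supported:

* HDF5 — ``/samples`` ``[n_channels x n_samples]`` in microvolts, with
  ``fs`` / ``subject_id`` attributes and an ``/annotations`` table;
* CSV — one column per channel, header row of channel names, a leading
  comment line carrying ``fs``;
* EDF — European Data Format, read through :mod:`mne`; written with a
  built-in minimal 16-bit writer (EDF quantises to integers, so the
  round trip is exact only for integer-valued microvolt data).
"""

from __future__ import annotations

import csv as _csv
import io
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

VOWELS = ("i", "e", "a", "o", "u")

#: 21-electrode montage of the extended 10-20 system (MCN labels).
MCN_21 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2", "TP7", "TP8",
)

ANNOTATION_KINDS = ("noise_lead_in", "imagery", "rest")


class SchemaError(ValueError):
    """A file parsed, but its contents violate the expected schema."""


@dataclass
class Annotation:
    onset_sample: int
    kind: str
    payload: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ANNOTATION_KINDS:
            raise SchemaError(f"unknown annotation kind {self.kind!r}")


@dataclass
class EEGRecording:
    """Multichannel time series in microvolts.

    ``samples`` is ``[n_channels x n_samples]``; ``fs`` in Hz.
    """

    samples: np.ndarray
    fs: float = 512.0
    channel_names: Sequence[str] = ()
    subject_id: str = ""
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] < 1:
            raise ValueError("samples must be a [n_channels x n_samples] matrix")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.n_channels))
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must match n_channels")
        if len(set(self.channel_names)) != self.n_channels:
            raise ValueError("channel names must be unique")
        for a in self.annotations:
            if not 0 <= a.onset_sample < self.n_samples:
                raise ValueError(f"annotation onset {a.onset_sample} outside recording")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class CorpusProtocol:
    """Syllable inventory plus per-vowel repetition counts.

    ``syllables`` is the row-major grid with ``None`` for empty cells.
    """

    syllables: list[list[str | None]]
    vowels: tuple[str, ...] = VOWELS
    repetitions_per_vowel: dict[str, int] = field(default_factory=dict)
    n_subjects: int = 5

    def __post_init__(self) -> None:
        for s in self.inventory():
            if s != "N" and syllable_vowel(s) not in self.vowels:
                raise SchemaError(f"syllable {s!r} has vowel outside inventory")

    def inventory(self) -> list[str]:
        """Non-empty cells, row-major order."""
        return [c for row in self.syllables for c in row if c is not None]

    @property
    def inventory_size(self) -> int:
        return len(self.inventory())


def syllable_vowel(syllable: str) -> str:
    """Vowel of a romaji CV syllable (its final letter); '' for the moraic nasal."""
    if syllable == "N":
        return ""
    return syllable[-1]


@dataclass
class SyllableLabel:
    """One labeled monosyllable chunk on the analysis-frame grid (0-based)."""

    start_frame: int
    n_frames: int
    syllable: str
    vowel: str
    is_pseudo: bool = False

    def __post_init__(self) -> None:
        if self.start_frame < 0:
            raise ValueError("start_frame must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.vowel and self.vowel not in VOWELS:
            raise SchemaError(f"unknown vowel {self.vowel!r}")


# ---------------------------------------------------------------------------
# protocol files

_HEADER_RE = re.compile(r"^#\s*(\w+):\s*(.*)$")


def load_protocol(path: str | Path | None = None) -> CorpusProtocol:
    """Load a protocol grid; with no path, the packaged 57-syllable inventory.

    The file is a plain-text grid, one row per vowel row of the
    inventory, cells separated by whitespace, ``-`` for an empty cell.
    Comment lines declare ``vowels``, per-vowel ``repetitions`` and the
    ``subjects`` count.
    """
    if path is None:
        text = (
            resources.files("neurovowel.data").joinpath("syllables_ja57.txt").read_text()
        )
    else:
        text = Path(path).read_text()

    vowels: tuple[str, ...] = VOWELS
    reps: dict[str, int] = {}
    n_subjects = 5
    grid: list[list[str | None]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        m = _HEADER_RE.match(line)
        if m:
            key, val = m.group(1), m.group(2).strip()
            if key == "vowels":
                vowels = tuple(val.split())
            elif key == "repetitions":
                for item in val.split():
                    v, n = item.split("=")
                    reps[v] = int(n)
            elif key == "subjects":
                n_subjects = int(val)
            continue
        if line.startswith("#"):
            continue
        cells = [None if c in ("-", "–") else c for c in line.split()]
        grid.append(cells)
    if not grid:
        raise SchemaError("protocol file contains no syllable grid")
    return CorpusProtocol(
        syllables=grid,
        vowels=vowels,
        repetitions_per_vowel=reps,
        n_subjects=n_subjects,
    )


def samples_per_subject(protocol: CorpusProtocol) -> int:
    """Total imagined-vowel samples per subject: sum of repetition counts."""
    missing = [v for v in protocol.vowels if v not in protocol.repetitions_per_vowel]
    if missing:
        raise SchemaError(f"repetition count missing for vowels {missing}")
    return sum(protocol.repetitions_per_vowel[v] for v in protocol.vowels)


# ---------------------------------------------------------------------------
# label files (TSV, one-line header, 0-based frames)

_LABEL_HEADER = "start_frame\tn_frames\tsyllable\tvowel\tis_pseudo"


def write_labels(labels: Sequence[SyllableLabel], path: str | Path) -> None:
    labels = sorted(labels, key=lambda l: l.start_frame)
    with open(path, "w") as fh:
        fh.write(_LABEL_HEADER + "\n")
        for l in labels:
            fh.write(
                f"{l.start_frame}\t{l.n_frames}\t{l.syllable}\t{l.vowel}\t{int(l.is_pseudo)}\n"
            )


def read_labels(path: str | Path) -> list[SyllableLabel]:
    out: list[SyllableLabel] = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != _LABEL_HEADER:
            raise SchemaError(f"unexpected label header {header!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            sf, nf, syl, vow, pseudo = line.split("\t")
            out.append(
                SyllableLabel(int(sf), int(nf), syl, vow, bool(int(pseudo)))
            )
    return sorted(out, key=lambda l: l.start_frame)


# ---------------------------------------------------------------------------
# recordings

def write_recording(rec: EEGRecording, path: str | Path, format: str | None = None) -> None:
    """Write a recording as HDF5, CSV or EDF (inferred from suffix if unset)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        _write_hdf5(rec, path)
    elif fmt == "csv":
        _write_csv(rec, path)
    elif fmt == "edf":
        _write_edf(rec, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_recording(path: str | Path, format: str | None = None) -> EEGRecording:
    """Read a recording written by :func:`write_recording` (or external EDF)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        return _read_hdf5(path)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown format {fmt!r}")


def _infer_format(path: Path) -> str:
    suf = path.suffix.lower()
    if suf in (".h5", ".hdf5"):
        return "hdf5"
    if suf == ".csv":
        return "csv"
    if suf == ".edf":
        return "edf"
    raise ValueError(f"cannot infer format from suffix {suf!r}")


def _write_hdf5(rec: EEGRecording, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("samples", data=rec.samples)
        d.attrs["units"] = "uV"
        f.attrs["fs"] = rec.fs
        f.attrs["subject_id"] = rec.subject_id
        f.attrs["channel_names"] = list(rec.channel_names)
        ann = np.array(
            [(a.onset_sample, a.kind, a.payload) for a in rec.annotations],
            dtype=[("onset_sample", "i8"), ("kind", "S16"), ("payload", "S64")],
        )
        f.create_dataset("annotations", data=ann)


def _read_hdf5(path: Path) -> EEGRecording:
    import h5py

    try:
        with h5py.File(path, "r") as f:
            samples = f["samples"][()]
            fs = float(f.attrs["fs"])
            subject = str(f.attrs.get("subject_id", ""))
            if "channel_names" not in f.attrs:
                raise SchemaError("HDF5 recording lacks channel_names attribute")
            names = [str(n) for n in f.attrs["channel_names"]]
            anns = [
                Annotation(int(r["onset_sample"]), r["kind"].decode(), r["payload"].decode())
                for r in f["annotations"][()]
            ]
    except OSError as e:
        raise IOError(f"unreadable HDF5 file {path}: {e}") from e
    return EEGRecording(samples, fs, names, subject, anns)


def _write_csv(rec: EEGRecording, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# fs={rec.fs} subject={rec.subject_id}\n")
        w = _csv.writer(fh)
        w.writerow(rec.channel_names)
        for row in rec.samples.T:
            w.writerow([repr(float(v)) for v in row])


def _read_csv(path: Path) -> EEGRecording:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise SchemaError("CSV recording must start with a '# fs=...' line")
        meta = dict(
            item.split("=", 1) for item in first.lstrip("#").split() if "=" in item
        )
        if "fs" not in meta:
            raise SchemaError("CSV recording header lacks fs")
        reader = _csv.reader(fh)
        names = next(reader, None)
        if not names:
            raise SchemaError("CSV recording lacks a channel-name header row")
        data = np.array([[float(v) for v in row] for row in reader])
    return EEGRecording(data.T, float(meta["fs"]), names, meta.get("subject", ""))


# -- EDF ---------------------------------------------------------------------
# Minimal EDF writer: one data record spanning the whole signal, 16-bit
# little-endian samples, physical units microvolts.  Physical range is
# chosen so that integer-valued data survives quantisation exactly.

def _write_edf(rec: EEGRecording, path: Path) -> None:
    n_sig = rec.n_channels
    n_samp = rec.n_samples
    if n_samp * 2 > 61440:
        raise ValueError("built-in EDF writer supports at most 30720 samples per channel")
    maxabs = float(np.max(np.abs(rec.samples))) if rec.samples.size else 1.0
    scale = max(1.0, math.ceil(maxabs / 32767.0))
    pmin, pmax = -32768.0 * scale, 32767.0 * scale
    digital = np.round(rec.samples / scale).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")[:n]
        return b + b" " * (n - len(b))

    duration = n_samp / rec.fs
    hdr = io.BytesIO()
    hdr.write(pad("0", 8))                                   # version
    hdr.write(pad(rec.subject_id or "X", 80))                # patient
    hdr.write(pad("neurovowel", 80))                         # recording id
    hdr.write(pad("01.01.00", 8))                            # start date
    hdr.write(pad("00.00.00", 8))                            # start time
    hdr.write(pad(str(256 + 256 * n_sig), 8))                # header bytes
    hdr.write(pad("", 44))                                   # reserved
    hdr.write(pad("1", 8))                                   # n data records
    hdr.write(pad(f"{duration:.6f}"[:8], 8))                 # record duration
    hdr.write(pad(str(n_sig), 4))
    for name in rec.channel_names:
        hdr.write(pad(name, 16))
    for _ in range(n_sig):
        hdr.write(pad("AgAgCl electrode", 80))
    for _ in range(n_sig):
        hdr.write(pad("uV", 8))
    for lim in (pmin, pmax):
        for _ in range(n_sig):
            hdr.write(pad(f"{lim:.1f}"[:8], 8))
    for lim in ("-32768", "32767"):
        for _ in range(n_sig):
            hdr.write(pad(lim, 8))
    for _ in range(n_sig):
        hdr.write(pad("", 80))                               # prefiltering
    for _ in range(n_sig):
        hdr.write(pad(str(n_samp), 8))                       # samples/record
    for _ in range(n_sig):
        hdr.write(pad("", 32))                               # reserved
    with open(path, "wb") as fh:
        fh.write(hdr.getvalue())
        fh.write(digital.tobytes())                          # signal-major


def _read_edf(path: Path) -> EEGRecording:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as e:  # mne raises assorted types for malformed files
        raise IOError(f"unreadable EDF file {path}: {e}") from e
    data = raw.get_data() * 1e6  # mne returns volts for EEG channels
    subject = ""
    if raw.info.get("subject_info"):
        subject = raw.info["subject_info"].get("his_id", "") or ""
    return EEGRecording(data, float(raw.info["sfreq"]), list(raw.ch_names), subject)
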