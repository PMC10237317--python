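"""Iterative PCA + subspace-method search for vowel spectra.

Each labeled chunk provides a block of candidate spectra (all
electrodes x the last 6 of its 9 frames).  Per vowel the search
alternates between scoring candidates against the current eigen-space
with the subspace-method similarity

    S(x) = sum_m <x, phi_m>^2 / (||x||^2 ||phi_m||^2),   m = 1..M

and refitting the eigenvectors by PCA on the best-scoring spectrum of
every chunk.  Four iterations of select-and-refit yield the final
eigen space psi(v, m) per vowel.

PCA here is *uncentered* (eigendecomposition of the second-moment
matrix): the similarity projects raw spectra, so centering would break
the property that a sample lying in the subspace scores S = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .eeg_io import VOWELS

DEFAULT_M = 8


@dataclass
class EigenSpace:
    """Top-M orthonormal eigenvectors of a vowel's spectrum second moment."""

    basis: np.ndarray  # [M, n_bins], rows orthonormal
    eigenvalues: np.ndarray  # descending, length M
    vowel: str = ""

    def __post_init__(self) -> None:
        self.basis = np.asarray(self.basis, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.basis.ndim != 2:
            raise ValueError("basis must be [M x n_bins]")
        if len(self.eigenvalues) != self.basis.shape[0]:
            raise ValueError("one eigenvalue per basis vector")
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be non-increasing")
        g = self.basis @ self.basis.T
        if not np.allclose(g, np.eye(self.M), atol=1e-8):
            raise ValueError("basis is not orthonormal")

    @property
    def M(self) -> int:
        return self.basis.shape[0]

    @property
    def n_bins(self) -> int:
        return self.basis.shape[1]


@dataclass(frozen=True)
class SearchConfig:
    """Iterative-search settings: 4 rounds, last 6 of 9 frames, M = 8."""

    n_iterations: int = 4
    search_last_k: int = 6
    chunk_frames: int = 9
    M: int = DEFAULT_M

    def __post_init__(self) -> None:
        if self.search_last_k > self.chunk_frames:
            raise ValueError("search window exceeds chunk length")
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")


def fit_pca(samples: np.ndarray, M: int, allow_fewer: bool = False) -> EigenSpace:
    """Top-M eigenvectors of the samples' uncentered second-moment matrix.

    ``samples`` is [n_samples x n_bins].  Eigenvalues are normalised by
    the sample count (mean squared projection per sample).  Eigenvector
    signs are fixed by making each vector's largest-magnitude component
    positive.  If the samples span fewer than M directions this raises,
    unless ``allow_fewer`` keeps the achieved rank instead (useful once
    an iterative search has concentrated the samples near a template).
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2:
        raise ValueError("samples must be [n x n_bins]")
    n, d = x.shape
    if n < M or d < M:
        raise ValueError(f"need at least M={M} samples and dimensions")
    smat = (x.T @ x) / n
    w, v = np.linalg.eigh(smat)
    order = np.argsort(w)[::-1][:M]
    w = w[order]
    v = v[:, order].T  # rows are eigenvectors
    rank = int(np.sum(w > max(w[0], 1e-300) * 1e-12))
    if rank < M:
        if not allow_fewer:
            raise np.linalg.LinAlgError(
                f"sample second moment has rank {rank}, need M={M}"
            )
        M = rank
        w = w[:M]
        v = v[:M]
    # deterministic sign: largest-|.| component positive
    for i in range(M):
        j = int(np.argmax(np.abs(v[i])))
        if v[i, j] < 0:
            v[i] = -v[i]
    return EigenSpace(v, w)


def similarity(x: np.ndarray, space: EigenSpace) -> float:
    """Subspace-method similarity of one spectrum; in [0, 1] for orthonormal bases."""
    x = np.asarray(x, dtype=float)
    nx = x @ x
    if nx == 0:
        raise ValueError("zero vector has no similarity")
    proj = space.basis @ x
    norms = np.sum(space.basis**2, axis=1)
    return float(np.sum(proj**2 / norms) / nx)


def similarity_batch(x: np.ndarray, space: EigenSpace) -> np.ndarray:
    """Similarity along the last axis for a batch [..., n_bins]; 0 for zero rows."""
    x = np.asarray(x, dtype=float)
    nx = np.sum(x**2, axis=-1)
    proj = x @ space.basis.T
    norms = np.sum(space.basis**2, axis=1)
    s = np.sum(proj**2 / norms, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(nx > 0, s / np.where(nx > 0, nx, 1.0), 0.0)


def eligible_frames(chunk: np.ndarray, cfg: SearchConfig) -> np.ndarray:
    """Restrict a [ch, frame, bin] chunk to the search window (last k frames)."""
    if chunk.ndim != 3:
        raise ValueError("chunk must be [ch x frame x bin]")
    k = min(cfg.search_last_k, chunk.shape[1])
    return chunk[:, chunk.shape[1] - k :, :]


def select_best_frame(
    chunk: np.ndarray, space: EigenSpace, cfg: SearchConfig | None = None
) -> tuple[np.ndarray, tuple[int, int]]:
    """Spectrum with maximal similarity over (electrode x last-k frames).

    Returns the winning sample and its (electrode, frame-within-chunk)
    indices.  Ties break to the earlier frame, then the lower electrode.
    """
    cfg = cfg or SearchConfig()
    win = eligible_frames(chunk, cfg)
    if not np.any(np.sum(win**2, axis=-1) > 0):
        raise ValueError("chunk has no nonzero spectra in the search window")
    s = similarity_batch(win, space)  # [ch, k]
    k = win.shape[1]
    # argmax with (frame, electrode) tie order: scan frame-major
    smax = s.max()
    frames_first = s.T  # [k, ch]
    flat = int(np.argmax(frames_first >= smax - 0.0))
    fr, ch = divmod(flat, s.shape[0])
    offset = chunk.shape[1] - k
    return win[ch, fr], (ch, offset + fr)


def _stack_window(chunks: Sequence[np.ndarray], cfg: SearchConfig) -> np.ndarray:
    rows = []
    for c in chunks:
        win = eligible_frames(np.asarray(c, dtype=float), cfg)
        rows.append(win.reshape(-1, win.shape[-1]))
    x = np.concatenate(rows, axis=0)
    return x[np.sum(x**2, axis=1) > 0]


@dataclass
class SearchTrace:
    """Per-iteration bookkeeping of the iterative search."""

    mean_similarity: list[float] = field(default_factory=list)


def search_vowel(
    chunks: Sequence[np.ndarray], cfg: SearchConfig | None = None, vowel: str = ""
) -> tuple[EigenSpace, SearchTrace]:
    """Iterative select-and-refit for one vowel's chunk collection."""
    cfg = cfg or SearchConfig()
    if len(chunks) < cfg.M:
        raise ValueError(
            f"vowel {vowel or '?'}: {len(chunks)} chunks, need at least M={cfg.M}"
        )
    space = fit_pca(_stack_window(chunks, cfg), cfg.M)
    trace = SearchTrace()
    for _ in range(cfg.n_iterations):
        selected = []
        sims = []
        for c in chunks:
            x, _ = select_best_frame(np.asarray(c, dtype=float), space, cfg)
            selected.append(x)
            sims.append(similarity(x, space))
        trace.mean_similarity.append(float(np.mean(sims)))
        space = fit_pca(np.asarray(selected), cfg.M, allow_fewer=True)
    space.vowel = vowel
    return space, trace


def iterative_search(
    corpus: Mapping[str, Sequence[np.ndarray]], cfg: SearchConfig | None = None
) -> tuple[dict[str, EigenSpace], dict[str, SearchTrace]]:
    """Run the per-vowel search for every vowel; deterministic in input order."""
    cfg = cfg or SearchConfig()
    spaces: dict[str, EigenSpace] = {}
    traces: dict[str, SearchTrace] = {}
    for v in VOWELS:
        if v not in corpus:
            continue
        spaces[v], traces[v] = search_vowel(corpus[v], cfg, vowel=v)
    missing = [v for v in corpus if v not in spaces]
    if missing:
        raise ValueError(f"unknown vowels in corpus: {missing}")
    return spaces, traces


def save_eigenspaces(spaces: Mapping[str, EigenSpace], path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for v, sp in spaces.items():
            g = f.create_group(f"vowel/{v}")
            g.create_dataset("basis", data=sp.basis)
            g.create_dataset("eigenvalues", data=sp.eigenvalues)
            g.attrs["M"] = sp.M


def load_eigenspaces(path: str | Path) -> dict[str, EigenSpace]:
    import h5py

    out: dict[str, EigenSpace] = {}
    with h5py.File(path, "r") as f:
        for v in f["vowel"]:
            g = f[f"vowel/{v}"]
            out[v] = EigenSpace(g["basis"][()], g["eigenvalues"][()], vowel=v)
    return out
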