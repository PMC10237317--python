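"""Vowel classifiers and leave-one-subject-out evaluation.

Two classifiers over chunk-level inputs:

* the subspace method (SM): a chunk is scored against every vowel's
  eigen space by the maximum subspace similarity over its candidate
  spectra (all electrodes x the last 6 frames), and the best vowel wins;
* a small 2-D CNN on the chunk's pooled line-spectrum image (last 6
  frames x pass-band bins).

Subject independence is evaluated by the jackknife: each subject is
held out once, classifiers are built from the remaining subjects, and
per-fold accuracies are summarised by mean and sample SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .eeg_io import VOWELS
from .labeling import pool_dense
from .nn import TinyCNN, TrainLog
from .vowel_search import (
    EigenSpace,
    SearchConfig,
    eligible_frames,
    iterative_search,
    similarity,
    similarity_batch,
)


@dataclass
class SMClassifier:
    """Subspace-method classifier: one eigen space per vowel."""

    spaces: dict[str, EigenSpace]

    def __post_init__(self) -> None:
        missing = [v for v in VOWELS if v not in self.spaces]
        if missing:
            raise ValueError(f"missing eigen spaces for vowels {missing}")
        dims = {s.n_bins for s in self.spaces.values()}
        if len(dims) != 1:
            raise ValueError("eigen spaces disagree on dimension")


def sm_classify(x: np.ndarray, clf: SMClassifier) -> str:
    """Vowel with the highest similarity for a single spectrum sample.

    Ties resolve in the fixed vowel order /i e a o u/.
    """
    scores = [similarity(x, clf.spaces[v]) for v in VOWELS]
    return VOWELS[int(np.argmax(scores))]


def sm_classify_chunk(
    chunk: np.ndarray, clf: SMClassifier, cfg: SearchConfig | None = None
) -> str:
    """Chunk decision: mean similarity over (electrode x last-k frames).

    Averaging over all candidate spectra of the chunk is markedly more
    robust than taking the single best-scoring one, whose value
    saturates for any sample lying near a vowel subspace.
    """
    cfg = cfg or SearchConfig()
    win = eligible_frames(np.asarray(chunk, dtype=float), cfg)
    scores = [float(similarity_batch(win, clf.spaces[v]).mean()) for v in VOWELS]
    return VOWELS[int(np.argmax(scores))]


@dataclass(frozen=True)
class CNNSpec:
    """Hyperparameters of the CNN classifier (desk-scale defaults)."""

    input_shape: tuple[int, int] = (6, 26)  # frames x pass-band bins
    conv_channels: tuple[int, ...] = (16, 32)
    kernel: int = 3
    dense_units: int = 64
    n_classes: int = 5
    seed: int = 0
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3


@dataclass
class CNNModel:
    net: TinyCNN
    spec: CNNSpec
    log: TrainLog


def chunk_to_image(chunk: np.ndarray, cfg: SearchConfig | None = None) -> np.ndarray:
    """CNN input image of a chunk: electrode-pooled last-k frames x bins."""
    cfg = cfg or SearchConfig()
    win = eligible_frames(np.asarray(chunk, dtype=float), cfg)
    return pool_dense(win)  # [k, n_bins]


def train_cnn(
    x: np.ndarray, y: Sequence[int] | np.ndarray, spec: CNNSpec | None = None
) -> CNNModel:
    """Train the CNN on labeled images [N, frames, bins]; deterministic per seed."""
    spec = spec or CNNSpec()
    y = np.asarray(y, dtype=int)
    present = set(y.tolist())
    absent = [c for c in range(spec.n_classes) if c not in present]
    if absent:
        raise ValueError(f"classes absent from training data: {absent}")
    net = TinyCNN(
        spec.input_shape,
        n_classes=spec.n_classes,
        conv_channels=spec.conv_channels,
        kernel=spec.kernel,
        dense_units=spec.dense_units,
        seed=spec.seed,
    )
    log = net.fit(
        x, y,
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        learning_rate=spec.learning_rate,
        seed=spec.seed,
    )
    return CNNModel(net, spec, log)


def cnn_classify(model: CNNModel, x: np.ndarray) -> tuple[str, np.ndarray]:
    """Predicted vowel and the softmax score vector (sums to 1)."""
    p = model.net.predict_proba(x)
    return VOWELS[int(np.argmax(p))], p


@dataclass
class FoldResult:
    """One jackknife fold: a held-out subject's accuracy and confusion."""

    held_out_subject: str
    n_train: int
    n_test: int
    accuracy: float  # percent
    confusion: np.ndarray  # [5 x 5] counts, rows = true vowel

    def __post_init__(self) -> None:
        total = self.confusion.sum()
        if total != self.n_test:
            raise ValueError("confusion total must equal n_test")
        acc = 100.0 * np.trace(self.confusion) / max(total, 1)
        if abs(acc - self.accuracy) > 1e-9:
            raise ValueError("accuracy must equal trace/total x 100")


@dataclass
class JackknifeSummary:
    folds: list[FoldResult]
    mean_accuracy: float
    sd_accuracy: float  # sample SD (n - 1)


SubjectData = Mapping[str, tuple[Sequence[np.ndarray], Sequence[str]]]


def _confusion(true: list[str], pred: list[str]) -> np.ndarray:
    m = np.zeros((5, 5), dtype=int)
    vi = {v: i for i, v in enumerate(VOWELS)}
    for t, p in zip(true, pred):
        m[vi[t], vi[p]] += 1
    return m


def jackknife_evaluate(
    corpus: SubjectData,
    classifier: str = "sm",
    search_cfg: SearchConfig | None = None,
    cnn_spec: CNNSpec | None = None,
) -> JackknifeSummary:
    """Leave-one-subject-out evaluation of the SM or CNN classifier.

    ``corpus`` maps subject -> (chunks, vowel labels), chunks being
    [electrode x frame x bin] tensors.  Every subject is held out
    exactly once; training pools all remaining subjects.
    """
    subjects = sorted(corpus)
    if len(subjects) < 2:
        raise ValueError("jackknife needs at least 2 subjects")
    for s in subjects:
        if len(corpus[s][0]) == 0:
            raise ValueError(f"subject {s} has no samples")
    search_cfg = search_cfg or SearchConfig()
    folds: list[FoldResult] = []
    for held in subjects:
        train_chunks: list[np.ndarray] = []
        train_labels: list[str] = []
        for s in subjects:
            if s == held:
                continue
            chunks, labels = corpus[s]
            train_chunks.extend(np.asarray(c, dtype=float) for c in chunks)
            train_labels.extend(labels)
        test_chunks, test_labels = corpus[held]
        test_labels = list(test_labels)
        if classifier == "sm":
            by_vowel: dict[str, list[np.ndarray]] = {v: [] for v in VOWELS}
            for c, l in zip(train_chunks, train_labels):
                by_vowel[l].append(c)
            spaces, _ = iterative_search(by_vowel, search_cfg)
            clf = SMClassifier(spaces)
            pred = [sm_classify_chunk(c, clf, search_cfg) for c in test_chunks]
        elif classifier == "cnn":
            spec = cnn_spec or CNNSpec()
            vi = {v: i for i, v in enumerate(VOWELS)}
            xtr = np.stack([chunk_to_image(c, search_cfg) for c in train_chunks])
            ytr = np.array([vi[l] for l in train_labels])
            model = train_cnn(xtr, ytr, spec)
            xte = np.stack([chunk_to_image(c, search_cfg) for c in test_chunks])
            p = model.net.predict_proba(xte)
            pred = [VOWELS[i] for i in p.argmax(axis=1)]
        else:
            raise ValueError(f"unknown classifier kind {classifier!r}")
        conf = _confusion(test_labels, pred)
        acc = 100.0 * np.trace(conf) / len(test_labels)
        folds.append(
            FoldResult(held, len(train_chunks), len(test_labels), acc, conf)
        )
    accs = np.array([f.accuracy for f in folds])
    sd = float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0
    return JackknifeSummary(folds, float(np.mean(accs)), sd)
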