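import numpy as np
import pytest

from neurovowel.eeg_io import MCN_21, EEGRecording
from neurovowel.pipeline import PipelineConfig, corpus_chunks
from neurovowel.synthgen import SynthConfig, synthesize_corpus


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def small_corpus():
    """Two subjects, 16 chunks per vowel — enough for cross-subject checks."""
    cfg = SynthConfig(n_subjects=2, chunks_per_vowel=16, seed=11)
    return synthesize_corpus(cfg)


@pytest.fixture(scope="session")
def small_corpus_chunks(small_corpus):
    """Preprocessed chunk tensors of the small corpus (expensive; shared)."""
    return corpus_chunks(small_corpus, PipelineConfig())


@pytest.fixture
def noise_recording(rng):
    x = rng.standard_normal((21, 1536))
    return EEGRecording(x, 512.0, MCN_21, "S99")
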