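"""Shared fixtures: corpora, vocabularies, and two trained models.

The two training runs (memorization on the tiny corpus, contrastive
clustering recovery on the scaffold-family corpus) are the expensive
fixtures of the suite; they are session-scoped so every test that
inspects a trained model reuses the same run.
"""

import numpy as np
import pytest

from fragnet import build_vocabulary, default_fixture
from fragnet.model import ModelConfig
from fragnet.training import train


@pytest.fixture(scope="session")
def tiny_corpus():
    return default_fixture("tiny")


@pytest.fixture(scope="session")
def small_corpus():
    return default_fixture("small")


@pytest.fixture(scope="session")
def small_vocab(small_corpus):
    return build_vocabulary(small_corpus, seed=0)


MEMO_CONFIG = dict(d_model=32, n_blocks=4, n_heads=4, max_len=24,
                   dropout=0.0, temperature=0.1, batch_size=5,
                   learning_rate=1e-3, epochs=2000, seed=7)
MEMO_STEPS = 2000

CLUSTER_CONFIG = dict(d_model=32, n_blocks=4, n_heads=4, max_len=64,
                      dropout=0.1, temperature=0.05, batch_size=8,
                      learning_rate=1e-3, epochs=1000, seed=11)
CLUSTER_STEPS = 700


@pytest.fixture(scope="session")
def memorized(tiny_corpus):
    """Model overfit on 5 short molecules (round-trip decoding fixture)."""
    cfg = ModelConfig(**MEMO_CONFIG)
    model, vocab, metrics = train(tiny_corpus, cfg, max_steps=MEMO_STEPS)
    return model, vocab, metrics


@pytest.fixture(scope="session")
def clustered(small_corpus):
    """Model trained contrastively on 3 scaffold families x 8 molecules."""
    cfg = ModelConfig(**CLUSTER_CONFIG)
    model, vocab, metrics = train(small_corpus, cfg, max_steps=CLUSTER_STEPS)
    return model, vocab, metrics
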