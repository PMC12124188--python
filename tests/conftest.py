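"""Shared fixtures: synthetic corpora, vocabularies, and the desk-scale
pre-trained checkpoint reused by the training-dependent tests."""

from __future__ import annotations

import numpy as np
import pytest

import smilescl as sc

# Desk-scale study conditions, shared between the test suite and the
# acceptance script: 2000 training molecules, width-64 two-layer encoder
# with 8 heads, batch 32, temperature 0.2, 5 epochs.
TINY_CORPUS_SEED = 42
TINY_ENCODER = dict(d_model=64, n_layers=2, n_heads=8, max_len=128,
                    vocab_size=300, seed=0)
TINY_PRETRAIN = dict(batch_size=32, temperature=0.2, learning_rate=1e-3,
                     epochs=5, seed=0)


@pytest.fixture(scope="session")
def corpus2000():
    spec = sc.CorpusSpec(n_molecules=2000, seed=TINY_CORPUS_SEED)
    return sc.generate_synthetic_corpus(spec)


@pytest.fixture(scope="session")
def vocab300(corpus2000):
    return sc.train_bpe(corpus2000, vocab_size=300)


@pytest.fixture(scope="session")
def small_corpus():
    return sc.generate_synthetic_corpus(sc.CorpusSpec(n_molecules=300, seed=11))


@pytest.fixture(scope="session")
def small_vocab(small_corpus):
    return sc.train_bpe(small_corpus, vocab_size=120)


@pytest.fixture(scope="session")
def tiny_encoder_config():
    return sc.EncoderConfig(**TINY_ENCODER)


@pytest.fixture(scope="session")
def tiny_checkpoint(corpus2000, vocab300, tiny_encoder_config):
    """Contrastively pre-trained desk-scale model plus its training log."""
    pre = sc.PretrainConfig(**TINY_PRETRAIN)
    model, log = sc.pretrain(corpus2000, tiny_encoder_config, pre,
                             vocab=vocab300)
    return model, log


@pytest.fixture(scope="session")
def heldout200(corpus2000):
    """200 synthetic molecules disjoint (by canonical form) from the
    pre-training corpus."""
    train_canon = {r.canonical for r in corpus2000}
    pool = sc.generate_synthetic_corpus(
        sc.CorpusSpec(n_molecules=2400, seed=4242))
    held = [r for r in pool if r.canonical not in train_canon][:200]
    assert len(held) == 200
    return held
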