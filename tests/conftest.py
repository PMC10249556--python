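"""Shared fixtures: small synthetic corpora and trained predictors.

Session-scoped fixtures are deliberately used for anything that trains a
model or builds a corpus, so the expensive artifacts are constructed once
and shared read-only across test modules.
"""

import numpy as np
import pytest

import mlmga as M


@pytest.fixture(scope="session")
def small_corpus() -> list[str]:
    """60 small C/N/O/F molecules — a fast, fully valid toy corpus."""
    return M.make_gdb9_like(60, seed=7)


@pytest.fixture(scope="session")
def small_vocab(small_corpus) -> M.TokenVocabulary:
    return M.build_vocabulary(small_corpus, target_size=96)


@pytest.fixture(scope="session")
def small_sequences(small_vocab, small_corpus):
    return [M.encode(small_vocab, s) for s in small_corpus]


@pytest.fixture(scope="session")
def ngram_model(small_vocab, small_sequences) -> M.NGramPredictor:
    model = M.NGramPredictor(small_vocab, seed=0)
    model.pretrain(small_sequences, epochs=1)
    return model


@pytest.fixture(scope="session")
def broad_setup():
    """The desk-scale study conditions: a 5,000-molecule drug-like corpus
    (synthesizability-filtered), a 512-token vocabulary, a 2-layer
    transformer pre-trained for 6 epochs, and the two initial populations
    (high-fitness "top" and low-fitness small-molecule sets, 500 each).

    Built once per session; used by the distribution and optimization
    experiments.
    """
    corpus = M.generate_corpus(M.CorpusSpec(n_molecules=5000, min_sa_norm=0.30, seed=11))
    vocab = M.build_vocabulary(corpus, target_size=512)
    sequences = [M.encode(vocab, s) for s in corpus]
    model = M.TransformerPredictor(vocab, M.TransformerConfig(), seed=0)
    model.pretrain(sequences, epochs=6, masking_rate=0.15)
    top = M.make_top_like(500, pool_factor=4, seed=12)
    gdb = M.make_gdb9_like(500, seed=13)
    return {
        "corpus": corpus,
        "vocab": vocab,
        "model": model,
        "base_state": model.state_dict(),
        "top": top,
        "gdb": gdb,
    }
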