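"""Shared fixtures: a small synthetic corpus with disjoint target
vocabularies and a tiny trained language model over it.

The corpus conditions (3 targets, 50 sentences each, disjoint word pools)
and the desk-scale model shape (hidden 32, 2 layers, 2 heads, 60 epochs)
are the study conditions used across the suite; session scope keeps the
model trained once.
"""

from __future__ import annotations

import numpy as np
import pytest

import bindtext as bt

RECOVERY_SPEC = bt.SyntheticSpec(
    n_targets=3, sentences_per_target=50, vocab_per_target=40,
    shared_vocab_fraction=0.0, sentence_length_range=(8, 24), seed=0,
)

TINY_LM = dict(hidden_size=32, n_layers=2, n_heads=2, batch_size=16,
               epochs=60, warmup_steps=20, seed=0)


@pytest.fixture(scope="session")
def synthetic_corpus():
    return bt.filter_sentences(bt.make_synthetic_corpus(RECOVERY_SPEC))


@pytest.fixture(scope="session")
def word_vocab(synthetic_corpus):
    return bt.build_word_vocab(synthetic_corpus)


@pytest.fixture(scope="session")
def max_len(synthetic_corpus, word_vocab):
    return bt.max_token_length(synthetic_corpus, word_vocab)


@pytest.fixture(scope="session")
def tokenized_samples(synthetic_corpus, word_vocab, max_len):
    return [bt.encode_sample(s, word_vocab, max_len) for s in synthetic_corpus]


@pytest.fixture(scope="session")
def trained_model(word_vocab, tokenized_samples, max_len):
    cfg = bt.LMConfig(max_seq_len=max_len, **TINY_LM)
    model = bt.init_model(cfg, len(word_vocab))
    bt.train(model, tokenized_samples, cfg)
    return model


@pytest.fixture(scope="session")
def logit_matrix(trained_model, synthetic_corpus, word_vocab, max_len):
    return bt.build_logit_matrix(trained_model, synthetic_corpus, word_vocab, max_len)


def make_bigram_corpus(n_words: int = 30, n_sentences: int = 60,
                       length: int = 12, seed: int = 7):
    """Corpus with a deterministic successor structure: every sentence walks
    the same cyclic word order from a random offset, so the word after any
    given word is always the same."""
    from bindtext.fixtures import _draw_unique_words

    rng = np.random.default_rng(seed)
    words = _draw_unique_words(rng, n_words)
    sentences = []
    for i in range(n_sentences):
        start = int(rng.integers(0, n_words))
        chain = [words[(start + j) % n_words] for j in range(length)]
        sentences.append(bt.BindingSentence(words=chain, target="BIGRAM",
                                            ligand_id="L", pose_id=str(i)))
    return words, sentences


def shuffle_words(sentences, seed: int = 11):
    """Destroy the successor structure by shuffling words within sentences."""
    rng = np.random.default_rng(seed)
    out = []
    for s in sentences:
        words = list(s.words)
        rng.shuffle(words)
        out.append(bt.BindingSentence(words=words, target=s.target,
                                      ligand_id=s.ligand_id, pose_id=s.pose_id))
    return out
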