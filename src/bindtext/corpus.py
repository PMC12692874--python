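"""Corpus preparation: filtering, splitting, and the two tokenization schemes.

Sentences with five or fewer words are discarded (short sentences reflect
non-specific poses), the remainder is split 7:2:1 into train/validation/test,
and tokenized either word-per-token or with a byte-pair-encoding tokenizer
learned on the corpus text.  Both schemes reserve [PAD]=0, [SEP]=1, [UNK]=2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .words import BindingSentence, parse_word

logger = logging.getLogger("bindtext")

PAD, SEP, UNK = "[PAD]", "[SEP]", "[UNK]"
PAD_ID, SEP_ID, UNK_ID = 0, 1, 2
SPECIALS = (PAD, SEP, UNK)

MIN_SENTENCE_WORDS = 6          # sentences shorter than this are dropped
DEFAULT_SPLIT = (0.7, 0.2, 0.1)


@dataclass
class Vocabulary:
    """Token <-> id bijection with the three reserved specials."""

    id_to_token: list[str]

    def __post_init__(self) -> None:
        if list(self.id_to_token[:3]) != list(SPECIALS):
            raise ValueError("ids 0,1,2 are reserved for [PAD], [SEP], [UNK]")
        self.token_to_id = {t: i for i, t in enumerate(self.id_to_token)}
        if len(self.token_to_id) != len(self.id_to_token):
            raise ValueError("vocabulary tokens must be unique")

    def __len__(self) -> int:
        return len(self.id_to_token)

    def id_of(self, token: str) -> int:
        return self.token_to_id.get(token, UNK_ID)

    def token_of(self, idx: int) -> str:
        return self.id_to_token[idx]

    def tokenize(self, sentence: BindingSentence) -> list[int]:
        """Word-level tokenization: one word, one token."""
        return [self.id_of(w) for w in sentence.word_strings]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"tokens": self.id_to_token}), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        return cls(json.loads(Path(path).read_text(encoding="utf-8"))["tokens"])


@dataclass
class TokenizedSample:
    """Fixed-length id sequence; positions >= n_real are [PAD]."""

    ids: np.ndarray
    n_real: int
    source: BindingSentence | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.n_real < 0 or self.n_real > self.ids.shape[0]:
            raise ValueError("n_real out of range")
        if np.any(self.ids[self.n_real:] != PAD_ID):
            raise ValueError("positions beyond n_real must be [PAD]")


# ---------------------------------------------------------------------------
# filtering and splitting
# ---------------------------------------------------------------------------

def filter_sentences(sentences: list[BindingSentence],
                     min_words: int = MIN_SENTENCE_WORDS) -> list[BindingSentence]:
    """Drop sentences with fewer than ``min_words`` words (default keeps
    length >= 6, i.e. excludes five-or-fewer-word sentences); order kept."""
    return [s for s in sentences if len(s) >= min_words]


def split_corpus(sentences: list, ratios: tuple[float, float, float] = DEFAULT_SPLIT,
                 seed: int = 0) -> tuple[list, list, list]:
    """Disjoint train/validation/test split by a seeded shuffle.

    Ratios are normalized; boundaries are cumulative-rounded so each part is
    within one item of N * ratio."""
    r = np.asarray(ratios, dtype=float)
    if np.any(r < 0) or r.sum() <= 0:
        raise ValueError("ratios must be non-negative with positive sum")
    r = r / r.sum()
    n = len(sentences)
    if n < np.count_nonzero(r):
        raise ValueError(f"cannot split {n} items into {np.count_nonzero(r)} non-empty parts")
    order = np.random.default_rng(seed).permutation(n)
    bounds = np.round(np.cumsum(r) * n).astype(int)
    bounds[-1] = n
    parts, start = [], 0
    for b in bounds:
        parts.append([sentences[i] for i in order[start:b]])
        start = b
    return tuple(parts)


# ---------------------------------------------------------------------------
# word-level vocabulary
# ---------------------------------------------------------------------------

def build_word_vocab(sentences: list[BindingSentence]) -> Vocabulary:
    """Every unique word string in the corpus becomes one token; ids follow
    first occurrence after the specials."""
    if not sentences:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    tokens = list(SPECIALS)
    seen = set(tokens)
    for s in sentences:
        for w in s.word_strings:
            if w not in seen:
                seen.add(w)
                tokens.append(w)
    return Vocabulary(tokens)


# ---------------------------------------------------------------------------
# byte-pair encoding
# ---------------------------------------------------------------------------

@dataclass
class BpeTokenizer:
    """Classic byte-pair encoding learned on space-separated corpus text.

    The base alphabet is the set of single characters (corpus text is ASCII,
    so characters and bytes coincide); merges never cross a whitespace
    boundary, and pure whitespace never enters the emitted token stream, so
    decoding a sample reproduces the sentence's non-whitespace content.
    """

    vocab: Vocabulary
    merges: list[tuple[str, str]] = field(default_factory=list)

    @classmethod
    def train(cls, corpus_text: str, target_vocab_size: int) -> "BpeTokenizer":
        words: dict[tuple[str, ...], int] = {}
        for line in corpus_text.splitlines():
            for w in line.split():
                key = tuple(w)
                words[key] = words.get(key, 0) + 1
        if not words:
            raise ValueError("empty corpus text")
        alphabet = sorted({c for w in words for c in w})
        if target_vocab_size < len(alphabet) + len(SPECIALS):
            raise ValueError(
                f"target vocabulary {target_vocab_size} smaller than base alphabet "
                f"({len(alphabet)}) plus specials")

        tokens = list(SPECIALS) + alphabet
        merges: list[tuple[str, str]] = []
        seqs = dict(words)
        while len(tokens) < target_vocab_size:
            pair_counts: dict[tuple[str, str], int] = {}
            for seq, cnt in seqs.items():
                for a, b in zip(seq, seq[1:]):
                    pair_counts[(a, b)] = pair_counts.get((a, b), 0) + cnt
            if not pair_counts:
                break   # merges exhausted: every word is a single symbol
            # most frequent pair; ties resolve to the lexicographically first
            _, a, b = min(((-cnt, a, b) for (a, b), cnt in pair_counts.items()))
            merged = a + b
            merges.append((a, b))
            tokens.append(merged)
            seqs = {cls._apply_merge(seq, a, b): cnt for seq, cnt in seqs.items()}
        return cls(vocab=Vocabulary(tokens), merges=merges)

    @staticmethod
    def _apply_merge(seq: tuple[str, ...], a: str, b: str) -> tuple[str, ...]:
        out, i = [], 0
        while i < len(seq):
            if i + 1 < len(seq) and seq[i] == a and seq[i + 1] == b:
                out.append(a + b)
                i += 2
            else:
                out.append(seq[i])
                i += 1
        return tuple(out)

    def _segment(self, word: str) -> list[str]:
        seq: tuple[str, ...] = tuple(word)
        for a, b in self.merges:
            seq = self._apply_merge(seq, a, b)
        return list(seq)

    def encode_text(self, text: str) -> list[int]:
        """Token ids for one paragraph; whitespace is a boundary only and is
        never emitted.  Characters outside the learned alphabet map to [UNK]."""
        ids: list[int] = []
        for w in text.split():
            for piece in self._segment(w):
                ids.append(self.vocab.id_of(piece))
        return ids

    def decode(self, ids: list[int]) -> str:
        return "".join(self.vocab.token_of(i) for i in ids
                       if i not in (PAD_ID, SEP_ID, UNK_ID))

    def tokenize(self, sentence: BindingSentence) -> list[int]:
        return self.encode_text(sentence.text)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"tokens": self.vocab.id_to_token, "merges": self.merges}), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "BpeTokenizer":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(vocab=Vocabulary(data["tokens"]),
                   merges=[tuple(m) for m in data["merges"]])


# ---------------------------------------------------------------------------
# fixed-length samples
# ---------------------------------------------------------------------------

def encode_sample(sentence: BindingSentence, vocab, max_seq_len: int,
                  on_overflow: str = "error") -> TokenizedSample:
    """Tokenize one sentence and pad with [PAD] to ``max_seq_len``.

    ``vocab`` is anything with a ``tokenize(sentence)`` method (a
    :class:`Vocabulary` or a :class:`BpeTokenizer`).  Over-length sentences
    raise by default; ``on_overflow='truncate'`` clips with a warning."""
    ids = vocab.tokenize(sentence)
    if len(ids) > max_seq_len:
        if on_overflow == "truncate":
            logger.warning("sentence truncated from %d to %d tokens", len(ids), max_seq_len)
            ids = ids[:max_seq_len]
        else:
            raise ValueError(f"sentence has {len(ids)} tokens > max_seq_len={max_seq_len}")
    n_real = len(ids)
    padded = np.full(max_seq_len, PAD_ID, dtype=np.int64)
    padded[:n_real] = ids
    return TokenizedSample(ids=padded, n_real=n_real, source=sentence)


def max_token_length(sentences: list[BindingSentence], vocab) -> int:
    """Default max_seq_len: the token count of the longest sample."""
    return max(len(vocab.tokenize(s)) for s in sentences)


# ---------------------------------------------------------------------------
# corpus text I/O (one paragraph per line, words space-separated)
# ---------------------------------------------------------------------------

def corpus_to_text(sentences: list[BindingSentence]) -> str:
    return "\n".join(s.text for s in sentences) + "\n"


def write_corpus(sentences: list[BindingSentence], path: str | Path) -> None:
    Path(path).write_text(corpus_to_text(sentences), encoding="utf-8")


def read_corpus(path: str | Path) -> list[BindingSentence]:
    sentences = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.strip():
            sentences.append(BindingSentence(words=[parse_word(w) for w in line.split()]))
    return sentences
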