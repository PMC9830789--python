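"""Byte-pair-encoding subword tokenizer.

Merges are learned greedily: at each step the most frequent adjacent symbol
pair over the (frequency-weighted) training words is merged into a new
symbol. Ties break lexicographically on the pair, so training is
deterministic. Learning stops when the requested vocabulary size is reached
or no pair occurs at least twice.

Encoding applies the learned merges in order, so every emitted token is in
the vocabulary; tokens concatenate back to the input word exactly
(detokenization is the inverse of tokenization).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from clinneg.errors import ConfigurationError

__all__ = ["SubwordTokenizer", "train_bpe", "PAD_TOKEN", "UNK_TOKEN"]

PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"


@dataclass
class SubwordTokenizer:
    """A trained BPE tokenizer.

    ``vocab`` maps every token (specials, alphabet characters and merged
    symbols) to a contiguous id. Specials always occupy the lowest ids,
    with ``<pad>`` at 0 and ``<unk>`` at 1.
    """

    merges: tuple[tuple[str, str], ...]
    vocab: dict[str, int]
    specials: tuple[str, ...] = (PAD_TOKEN, UNK_TOKEN)

    @property
    def pad_id(self) -> int:
        return self.vocab[PAD_TOKEN]

    @property
    def unk_id(self) -> int:
        return self.vocab[UNK_TOKEN]

    def add_special(self, token: str) -> int:
        """Register an extra special token (e.g. an entity placeholder).

        The token must not collide with the learned vocabulary. Idempotent.
        """
        if token in self.vocab:
            if token in self.specials:
                return self.vocab[token]
            raise ConfigurationError(f"special token {token!r} collides with corpus vocabulary")
        idx = len(self.vocab)
        self.vocab[token] = idx
        self.specials = self.specials + (token,)
        return idx

    # -- encoding -----------------------------------------------------------

    def encode_word(self, word: str) -> list[str]:
        """Subword tokens of one word; ``"".join(result) == word``."""
        if not word:
            return []
        symbols = list(word)
        for a, b in self.merges:
            if len(symbols) < 2:
                break
            merged: list[str] = []
            i = 0
            while i < len(symbols):
                if i + 1 < len(symbols) and symbols[i] == a and symbols[i + 1] == b:
                    merged.append(a + b)
                    i += 2
                else:
                    merged.append(symbols[i])
                    i += 1
            symbols = merged
        return symbols

    def tokenize(self, text: str) -> list[str]:
        """Subword tokens of whitespace-split ``text`` (flattened)."""
        out: list[str] = []
        for word in text.split():
            out.extend(self.encode_word(word))
        return out

    def encode_ids(self, tokens: Sequence[str]) -> list[int]:
        """Map token strings to ids; unknown tokens map to ``<unk>``."""
        unk = self.unk_id
        return [self.vocab.get(t, unk) for t in tokens]


def _pair_counts(seqs: dict[tuple[str, ...], int]) -> Counter:
    counts: Counter = Counter()
    for seq, freq in seqs.items():
        for i in range(len(seq) - 1):
            counts[(seq[i], seq[i + 1])] += freq
    return counts


def _merge_seq(seq: tuple[str, ...], pair: tuple[str, str]) -> tuple[str, ...]:
    a, b = pair
    out: list[str] = []
    i = 0
    while i < len(seq):
        if i + 1 < len(seq) and seq[i] == a and seq[i + 1] == b:
            out.append(a + b)
            i += 2
        else:
            out.append(seq[i])
            i += 1
    return tuple(out)


def train_bpe(corpus_texts: Iterable[str], vocab_size: int) -> SubwordTokenizer:
    """Learn a BPE tokenizer from raw texts.

    ``vocab_size`` counts alphabet characters plus merged symbols (special
    tokens come on top). It must be at least the alphabet size; when equal,
    no merges are learned and tokenization is character-level.
    """
    word_freq: Counter = Counter()
    for text in corpus_texts:
        word_freq.update(text.split())
    if not word_freq:
        raise ConfigurationError("BPE training corpus is empty")

    alphabet = sorted({ch for word in word_freq for ch in word})
    if vocab_size < len(alphabet):
        raise ConfigurationError(
            f"vocab_size {vocab_size} is smaller than the alphabet size {len(alphabet)}"
        )

    seqs: dict[tuple[str, ...], int] = {}
    for word, freq in sorted(word_freq.items()):
        seqs[tuple(word)] = seqs.get(tuple(word), 0) + freq

    symbols: list[str] = list(alphabet)
    merges: list[tuple[str, str]] = []
    while len(symbols) < vocab_size:
        counts = _pair_counts(seqs)
        if not counts:
            break
        best_count = max(counts.values())
        if best_count < 2:
            break
        # deterministic tie-break: lexicographically smallest pair
        best = min(p for p, c in counts.items() if c == best_count)
        merges.append(best)
        symbols.append(best[0] + best[1])
        seqs = {_merge_seq(seq, best): freq for seq, freq in seqs.items()}

    vocab = {PAD_TOKEN: 0, UNK_TOKEN: 1}
    for sym in symbols:
        vocab[sym] = len(vocab)
    return SubwordTokenizer(merges=tuple(merges), vocab=vocab)
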