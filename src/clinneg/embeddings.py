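"""Continuous-bag-of-words embedding pretraining (pure numpy).

The objective predicts a center token from the average of its context
vectors via a full softmax (vocabularies here are small). Training is plain
SGD, reproducible under a fixed seed; per-epoch mean losses are recorded on
the returned table.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from dataclasses import dataclass, field

from clinneg.errors import ConfigurationError
from clinneg.subword import SubwordTokenizer

__all__ = ["EmbeddingTable", "pretrain_cbow"]


@dataclass
class EmbeddingTable:
    """Vocabulary-indexed embedding vectors of fixed dimension."""

    tokens: list[str]
    vectors: np.ndarray  # (V, dim), float64
    epoch_losses: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.tokens):
            raise ConfigurationError("embedding table shape does not match vocabulary")
        if not np.all(np.isfinite(self.vectors)):
            raise ConfigurationError("embedding table contains non-finite values")
        self.index = {tok: i for i, tok in enumerate(self.tokens)}

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    def get(self, token: str) -> np.ndarray | None:
        i = self.index.get(token)
        return None if i is None else self.vectors[i]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def pretrain_cbow(
    corpus_texts: Iterable[str],
    dim: int,
    context_window: int = 5,
    seed: int = 0,
    epochs: int = 5,
    lr: float = 0.05,
    tokenizer: SubwordTokenizer | None = None,
) -> EmbeddingTable:
    """Train CBOW embeddings on raw texts.

    Tokens are subword tokens when ``tokenizer`` is given, otherwise
    whitespace tokens. One vector per vocabulary token is returned; values
    are finite by construction and training is deterministic under ``seed``.
    """
    if dim <= 0:
        raise ConfigurationError(f"embedding dim must be >= 1, got {dim}")
    if context_window < 1:
        raise ConfigurationError(f"context_window must be >= 1, got {context_window}")

    sentences: list[list[str]] = []
    for text in corpus_texts:
        toks = tokenizer.tokenize(text) if tokenizer is not None else text.split()
        if toks:
            sentences.append(toks)
    if not sentences:
        raise ConfigurationError("CBOW training corpus is empty")

    vocab = sorted({t for sent in sentences for t in sent})
    index = {t: i for i, t in enumerate(vocab)}
    V = len(vocab)

    rng = np.random.default_rng(seed)
    W_in = (rng.random((V, dim)) - 0.5) / dim
    W_out = (rng.random((V, dim)) - 0.5) / dim

    ids = [np.array([index[t] for t in sent], dtype=np.int64) for sent in sentences]

    epoch_losses: list[float] = []
    for _epoch in range(epochs):
        total, count = 0.0, 0
        for sent in ids:
            n = len(sent)
            for pos in range(n):
                lo = max(0, pos - context_window)
                hi = min(n, pos + context_window + 1)
                ctx = np.concatenate([sent[lo:pos], sent[pos + 1 : hi]])
                if len(ctx) == 0:
                    continue
                center = sent[pos]
                h = W_in[ctx].mean(axis=0)
                probs = _softmax(W_out @ h)
                total += -float(np.log(probs[center] + 1e-12))
                count += 1
                dz = probs
                dz[center] -= 1.0
                dh = W_out.T @ dz
                W_out -= lr * np.outer(dz, h)
                W_in[ctx] -= lr * dh / len(ctx)
        epoch_losses.append(total / max(count, 1))
    return EmbeddingTable(tokens=vocab, vectors=W_in, epoch_losses=epoch_losses)
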