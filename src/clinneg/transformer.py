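"""Entity-centered token windows and subword score aggregation.

This module provides the transformer-side plumbing without any transformer:
variable-size token windows under a maximum sequence length, the rule that
in validation only the center entity of a window counts, and aggregation of
per-subword negation probabilities up to words and entities. Any external
pretrained scorer (or a mock) satisfying the :class:`WindowScorer` protocol
can be plugged in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

from clinneg.corpus import ContextPrediction
from clinneg.errors import AlignmentError, ClinnegError, ConfigurationError, ValidationError

__all__ = [
    "SequenceLimit",
    "TokenWindow",
    "TokenScoreVector",
    "WindowScorer",
    "ScorerError",
    "build_token_windows",
    "aggregate_word_score",
    "score_with_adapter",
]


@dataclass(frozen=True)
class SequenceLimit:
    max_sequence_length: int = 512

    def __post_init__(self) -> None:
        if self.max_sequence_length < 1:
            raise ConfigurationError("max_sequence_length must be positive")


@dataclass(frozen=True)
class TokenWindow:
    """A document token range centered on one entity."""

    token_start: int  # document token index, inclusive
    token_end: int  # exclusive
    entity_index: int
    entity_token_range: tuple[int, int]
    role: str  # "training" | "validation"

    def __len__(self) -> int:
        return self.token_end - self.token_start


def build_token_windows(
    n_doc_tokens: int,
    entities: Sequence[tuple[int, int]],
    limit: SequenceLimit,
    mode: str = "validation",
) -> list[TokenWindow]:
    """One window per entity, centered on it, never exceeding the limit.

    Centering convention: the left side gets ``limit // 2`` tokens; when the
    window is clipped at a document edge the surplus goes to the other side.
    In training mode windows may overlap (an entity can fall inside another
    entity's window); in validation mode each entity is the center of
    exactly one window and only that entity counts for that window.
    """
    if mode not in ("training", "validation"):
        raise ConfigurationError(f"mode must be 'training' or 'validation', got {mode!r}")
    L = limit.max_sequence_length
    windows = []
    for ei, (lo, hi) in enumerate(entities):
        if not (0 <= lo < hi <= n_doc_tokens):
            raise ValidationError(
                f"entity {ei} token range [{lo}, {hi}) outside document of {n_doc_tokens} tokens"
            )
        center = (lo + hi - 1) // 2
        start = center - L // 2
        end = start + L
        if start < 0:
            end += -start
            start = 0
        if end > n_doc_tokens:
            start -= end - n_doc_tokens
            end = n_doc_tokens
        start = max(start, 0)
        windows.append(
            TokenWindow(
                token_start=start,
                token_end=end,
                entity_index=ei,
                entity_token_range=(lo, hi),
                role=mode,
            )
        )
    return windows


@dataclass(frozen=True)
class TokenScoreVector:
    """Per-subword-token negation probabilities with subword-to-word alignment.

    ``word_index[i]`` is the (window-local) word each subword token ``i``
    belongs to; every subword token must be aligned.
    """

    probabilities: tuple[float, ...]
    word_index: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.probabilities) != len(self.word_index):
            raise AlignmentError(
                f"{len(self.probabilities)} probabilities but {len(self.word_index)} alignments"
            )
        for p in self.probabilities:
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"token probability {p} outside [0, 1]")


def aggregate_word_score(scores: TokenScoreVector, word: int, mode: str = "max") -> float:
    """Collapse the subword probabilities of one word to a single probability.

    ``max`` takes the maximum probability over the word's tokens; ``mean``
    the arithmetic mean.
    """
    vals = [p for p, w in zip(scores.probabilities, scores.word_index) if w == word]
    if not vals:
        raise AlignmentError(f"word {word} has no aligned subword tokens")
    if mode == "max":
        return max(vals)
    if mode == "mean":
        return sum(vals) / len(vals)
    raise ConfigurationError(f"unknown aggregation mode {mode!r}")


class WindowScorer(Protocol):
    """External scoring interface: maps a token window to per-token scores."""

    def __call__(self, window: TokenWindow) -> TokenScoreVector: ...


class ScorerError(ClinnegError):
    """Scorer failure, tagged with the window it occurred on."""

    def __init__(self, window: TokenWindow, cause: Exception):
        self.window = window
        super().__init__(
            f"scorer failed on window [{window.token_start}, {window.token_end}) "
            f"for entity {window.entity_index}: {cause}"
        )


def score_with_adapter(
    scorer: WindowScorer,
    windows: Sequence[TokenWindow],
    doc_id: str,
    aggregation: str = "max",
    threshold: float = 0.5,
) -> list[ContextPrediction]:
    """Per-entity predictions from aggregated center-entity scores.

    For each window the scorer yields per-subword probabilities; these are
    aggregated per word (``aggregation`` mode), and the entity probability is
    the maximum over its words. Label is ``negated`` iff the probability is
    >= ``threshold``. Predictions carry ``method="transformer"``.
    """
    predictions = []
    for window in windows:
        try:
            scores = scorer(window)
        except Exception as exc:  # propagate with window identity attached
            raise ScorerError(window, exc) from exc
        lo, hi = window.entity_token_range
        word_scores = [
            aggregate_word_score(scores, w - window.token_start, mode=aggregation)
            for w in range(lo, hi)
        ]
        prob = max(word_scores)
        predictions.append(
            ContextPrediction.from_probability(
                doc_id, window.entity_index, prob, method="transformer", threshold=threshold
            )
        )
    return predictions
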