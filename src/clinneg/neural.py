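"""Recurrent negation classifier: windows, placeholder abstraction, training.

The pipeline mirrors the MetaCAT-style setup: word tokens around each
annotated term are windowed (15 left / 10 right by default), the term itself
is replaced by a single placeholder token, words are broken into BPE
subwords, and a bidirectional recurrent network with a fully-connected head
maps the id sequence to a negation probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from clinneg.corpus import AnnotatedDocument, ContextPrediction, NegationLabel
from clinneg.embeddings import EmbeddingTable
from clinneg.errors import ConfigurationError, ValidationError
from clinneg.recurrent import BiLSTMNetwork, HyperParams
from clinneg.rules import tokenize
from clinneg.subword import SubwordTokenizer, train_bpe

__all__ = [
    "WindowConfig",
    "TrainingExample",
    "ContextClassifier",
    "abstract_entity",
    "make_example",
    "examples_from_corpus",
    "train_classifier",
    "predict",
]

PLACEHOLDER = "[TERM]"


@dataclass(frozen=True)
class WindowConfig:
    """Asymmetric token window around the annotated term.

    Windows are counted in *word* tokens before subword encoding, so the
    15/10 semantics do not depend on the BPE vocabulary size.
    """

    left_tokens: int = 15
    right_tokens: int = 10
    placeholder_symbol: str = PLACEHOLDER

    def __post_init__(self) -> None:
        if self.left_tokens < 0 or self.right_tokens < 0:
            raise ConfigurationError("window sizes must be non-negative")
        if not self.placeholder_symbol:
            raise ConfigurationError("placeholder symbol must be non-empty")


@dataclass(frozen=True)
class TrainingExample:
    """Subword id sequence with exactly one placeholder, plus its label.

    ``doc_id``/``entity_index`` are provenance for turning predictions back
    into per-entity records; they do not affect the model input.
    """

    token_ids: tuple[int, ...]
    placeholder_index: int
    label: NegationLabel | None = None
    doc_id: str = ""
    entity_index: int = -1

    def __post_init__(self) -> None:
        if not (0 <= self.placeholder_index < len(self.token_ids)):
            raise ValidationError("placeholder index outside the token sequence")


def abstract_entity(
    tokens: Sequence[str], entity_token_range: tuple[int, int], config: WindowConfig
) -> list[str]:
    """Replace the entity tokens with one placeholder and clip the window.

    ``entity_token_range`` is a half-open range into ``tokens``. Up to
    ``left_tokens`` before and ``right_tokens`` after the entity are
    retained, clipped at the document edges.
    """
    lo, hi = entity_token_range
    if not (0 <= lo < hi <= len(tokens)):
        raise ValidationError(
            f"entity token range [{lo}, {hi}) invalid for {len(tokens)} tokens"
        )
    left = list(tokens[max(0, lo - config.left_tokens) : lo])
    right = list(tokens[hi : hi + config.right_tokens])
    return left + [config.placeholder_symbol] + right


def _entity_token_range(
    token_spans: Sequence[tuple[int, int]], start: int, end: int
) -> tuple[int, int]:
    idxs = [i for i, (ts, te) in enumerate(token_spans) if ts < end and te > start]
    if not idxs:
        raise ValidationError(f"entity span [{start}, {end}) covers no token")
    return idxs[0], idxs[-1] + 1


def make_example(
    text: str,
    entity_span: tuple[int, int],
    tokenizer: SubwordTokenizer,
    config: WindowConfig,
    label: NegationLabel | None = None,
    doc_id: str = "",
    entity_index: int = -1,
) -> TrainingExample:
    """Window + abstract + subword-encode one entity occurrence."""
    spans = tokenize(text)
    rng_ = _entity_token_range(spans, *entity_span)
    words = [text[s:e] for s, e in spans]
    window = abstract_entity(words, rng_, config)
    placeholder_id = tokenizer.add_special(config.placeholder_symbol)
    ids: list[int] = []
    placeholder_index = -1
    for w in window:
        if w == config.placeholder_symbol:
            placeholder_index = len(ids)
            ids.append(placeholder_id)
        else:
            ids.extend(tokenizer.encode_ids(tokenizer.encode_word(w)))
    return TrainingExample(
        token_ids=tuple(ids),
        placeholder_index=placeholder_index,
        label=label,
        doc_id=doc_id,
        entity_index=entity_index,
    )


def examples_from_corpus(
    docs: Iterable[AnnotatedDocument],
    tokenizer: SubwordTokenizer,
    config: WindowConfig | None = None,
    require_labels: bool = True,
) -> list[TrainingExample]:
    """One example per entity over a corpus, using gold labels when present."""
    config = config or WindowConfig()
    examples = []
    for doc in docs:
        for ei, ent in enumerate(doc.entities):
            if require_labels and ent.gold_label is None:
                raise ValidationError(f"entity {ei} has no gold label", doc_id=doc.doc_id)
            examples.append(
                make_example(
                    doc.text,
                    (ent.start, ent.end),
                    tokenizer,
                    config,
                    label=ent.gold_label,
                    doc_id=doc.doc_id,
                    entity_index=ei,
                )
            )
    return examples


@dataclass
class ContextClassifier:
    """Trained recurrent context classifier with its tokenizer and config."""

    network: BiLSTMNetwork
    tokenizer: SubwordTokenizer
    window: WindowConfig
    hyperparams: HyperParams
    threshold: float = 0.5
    epoch_losses: list[float] = field(default_factory=list)

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Persist to a directory: config manifest, tokenizer, weights."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": 1,
            "threshold": self.threshold,
            "window": asdict(self.window),
            "hyperparams": asdict(self.hyperparams),
            "epoch_losses": self.epoch_losses,
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
        tok = {
            "merges": [list(m) for m in self.tokenizer.merges],
            "vocab": self.tokenizer.vocab,
            "specials": list(self.tokenizer.specials),
        }
        (d / "tokenizer.json").write_text(json.dumps(tok, ensure_ascii=False), encoding="utf-8")
        np.savez(d / "weights.npz", **self.network.state_dict())

    @classmethod
    def load(cls, directory: str | Path) -> "ContextClassifier":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text(encoding="utf-8"))
        tok_raw = json.loads((d / "tokenizer.json").read_text(encoding="utf-8"))
        tokenizer = SubwordTokenizer(
            merges=tuple(tuple(m) for m in tok_raw["merges"]),
            vocab={k: int(v) for k, v in tok_raw["vocab"].items()},
            specials=tuple(tok_raw["specials"]),
        )
        hp = HyperParams(**manifest["hyperparams"])
        window = WindowConfig(**manifest["window"])
        network = BiLSTMNetwork(len(tokenizer.vocab), hp, np.random.default_rng(0))
        with np.load(d / "weights.npz") as state:
            network.load_state_dict({k: state[k].copy() for k in state.files})
        return cls(
            network=network,
            tokenizer=tokenizer,
            window=window,
            hyperparams=hp,
            threshold=float(manifest["threshold"]),
            epoch_losses=list(manifest.get("epoch_losses", [])),
        )


def _pad_batch(
    examples: Sequence[TrainingExample], pad_id: int, max_len: int
) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.array([min(len(ex.token_ids), max_len) for ex in examples], dtype=np.int64)
    T = max(int(lengths.max()), 1)
    ids = np.full((len(examples), T), pad_id, dtype=np.int64)
    for r, ex in enumerate(examples):
        seq = ex.token_ids[: lengths[r]]
        ids[r, : len(seq)] = seq
    return ids, lengths


def train_classifier(
    examples: Sequence[TrainingExample],
    tokenizer: SubwordTokenizer,
    embeddings: EmbeddingTable | None = None,
    hyperparams: HyperParams | None = None,
    seed: int = 0,
    window: WindowConfig | None = None,
) -> ContextClassifier:
    """Train the recurrent classifier on placeholder-abstracted examples.

    Requires at least one example per class. When a pretrained embedding
    table is given, rows for tokens present in the table are copied in
    (others stay randomly initialized); its dimension overrides
    ``hyperparams.emb_dim``.
    """
    hp = hyperparams or HyperParams()
    window = window or WindowConfig()
    labels = {ex.label for ex in examples}
    for needed in (NegationLabel.NEGATED, NegationLabel.NOT_NEGATED):
        if needed not in labels:
            raise ValidationError(f"training set lacks the class {needed.value!r}")

    vocab_size = len(tokenizer.vocab)
    rng = np.random.default_rng(seed)
    emb_init = None
    if embeddings is not None:
        hp.emb_dim = embeddings.dim
        emb_init = (rng.random((vocab_size, hp.emb_dim)) - 0.5) / hp.emb_dim
        for tok, idx in tokenizer.vocab.items():
            vec = embeddings.get(tok)
            if vec is not None:
                emb_init[idx] = vec
    network = BiLSTMNetwork(vocab_size, hp, rng, embedding_init=emb_init)

    ids, lengths = _pad_batch(examples, tokenizer.pad_id, hp.max_len)
    y = np.array([1 if ex.label is NegationLabel.NEGATED else 0 for ex in examples])
    losses = network.fit(ids, lengths, y, seed=seed)
    return ContextClassifier(
        network=network,
        tokenizer=tokenizer,
        window=window,
        hyperparams=hp,
        epoch_losses=losses,
    )


def predict(
    classifier: ContextClassifier, examples: TrainingExample | Sequence[TrainingExample]
) -> list[ContextPrediction]:
    """Score examples; label is ``negated`` iff probability >= threshold.

    Out-of-vocabulary ids were already mapped to the reserved unknown token
    during encoding; anything out of range here is clamped to it as well.
    """
    single = isinstance(examples, TrainingExample)
    batch = [examples] if single else list(examples)
    if not batch:
        return []
    ids, lengths = _pad_batch(batch, classifier.tokenizer.pad_id, classifier.hyperparams.max_len)
    vocab_size = len(classifier.tokenizer.vocab)
    bad = (ids < 0) | (ids >= vocab_size)
    if bad.any():
        ids = np.where(bad, classifier.tokenizer.unk_id, ids)
    probs = classifier.network.predict_proba(ids, lengths)
    out = []
    for ex, p in zip(batch, probs):
        out.append(
            ContextPrediction.from_probability(
                ex.doc_id, ex.entity_index, float(p), method="bilstm",
                threshold=classifier.threshold,
            )
        )
    return out
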