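"""Labeled synthetic clinical-like corpus generator.

Documents are assembled sentence by sentence from invented term-like
strings, neutral filler words and a trigger grammar aligned with the rule
lexicon. Every entity carries a ground-truth trace stating the mechanism
that produced its label, so generated labels are sound by construction:
negated entities arise only from a forward trigger preceding the entity
within its sentence, a backward trigger following it, or (with noise
enabled) minus shorthand.

Category realism is statistical only: per-category sentence/word length
targets, an overall negation prevalence, and over-dispersed (negative
binomial) sentence counts. No real patient-derived text is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np

from clinneg.corpus import (
    AnnotatedDocument,
    EntityAnnotation,
    NegationLabel,
    RecordCategory,
)
from clinneg.errors import ConfigurationError
from clinneg.rules import TriggerCategory, TriggerEntry, TriggerLexicon

__all__ = [
    "CategoryProfile",
    "NoiseRates",
    "GeneratorConfig",
    "GroundTruthTrace",
    "generate_corpus",
    "inject_noise",
    "default_grammar",
]


@dataclass(frozen=True)
class CategoryProfile:
    """Length targets for one record category (means per record)."""

    mean_sentences: float
    mean_words: float


DEFAULT_PROFILES: dict[RecordCategory, CategoryProfile] = {
    RecordCategory.GENERAL_PRACTITIONER: CategoryProfile(2.1, 17.8),
    RecordCategory.SPECIALIST_LETTER: CategoryProfile(3.8, 30.0),
    RecordCategory.RADIOLOGY_REPORT: CategoryProfile(3.6, 19.1),
    RecordCategory.DISCHARGE_LETTER: CategoryProfile(4.1, 33.8),
}

DEFAULT_CATEGORY_MIX: dict[RecordCategory, float] = {
    RecordCategory.GENERAL_PRACTITIONER: 2034.0,
    RecordCategory.SPECIALIST_LETTER: 2737.0,
    RecordCategory.RADIOLOGY_REPORT: 3939.0,
    RecordCategory.DISCHARGE_LETTER: 3057.0,
}


@dataclass(frozen=True)
class NoiseRates:
    minus: float = 0.0
    missing_whitespace: float = 0.0
    punctuation: float = 0.0

    def any(self) -> bool:
        return self.minus > 0 or self.missing_whitespace > 0 or self.punctuation > 0


def _read_wordlist(name: str) -> list[str]:
    ref = resources.files("clinneg").joinpath(f"wordlists/{name}")
    words = []
    for line in ref.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.append(line)
    return words


def default_grammar() -> list[TriggerEntry]:
    """Trigger inventory aligned with the packaged rule lexicon: all literal
    negation and termination entries without a word-count scope limit."""
    out = []
    for entry in TriggerLexicon.default().entries:
        if entry.category is TriggerCategory.PSEUDO or entry.max_scope is not None:
            continue
        out.append(entry)
    return out


@dataclass
class GeneratorConfig:
    n_documents: int = 100
    category_mix: dict[RecordCategory, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX)
    )
    negation_prevalence: float = 0.14
    entity_rate: float = 0.8  # probability a sentence contains one entity
    triggers: list[TriggerEntry] = field(default_factory=default_grammar)
    trigger_weights: dict[str, float] | None = None
    noise: NoiseRates = field(default_factory=NoiseRates)
    profiles: dict[RecordCategory, CategoryProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_documents < 1:
            problems.append("n_documents must be >= 1")
        if not (0.0 <= self.negation_prevalence <= 1.0):
            problems.append("negation_prevalence must be in [0, 1]")
        if not (0.0 <= self.entity_rate <= 1.0):
            problems.append("entity_rate must be in [0, 1]")
        for name in ("minus", "missing_whitespace", "punctuation"):
            r = getattr(self.noise, name)
            if not (0.0 <= r <= 1.0):
                problems.append(f"noise rate {name} must be in [0, 1]")
        if not self.category_mix or any(w < 0 for w in self.category_mix.values()):
            problems.append("category_mix must give non-negative weights")
        for cat, prof in self.profiles.items():
            if prof.mean_sentences <= 0 or prof.mean_words <= 0:
                problems.append(f"length targets for {cat.value} must be positive")
        if not any(
            e.category in (TriggerCategory.NEGATION_FORWARD, TriggerCategory.NEGATION_BACKWARD)
            for e in self.triggers
        ):
            problems.append("trigger grammar needs at least one negation trigger")
        if problems:
            raise ConfigurationError("invalid generator config: " + "; ".join(problems))


@dataclass
class GroundTruthTrace:
    """Per-entity provenance: the mechanism that generated its label."""

    doc_id: str
    entity_index: int
    label: NegationLabel
    mechanism: str  # forward_trigger | backward_trigger | terminated | pre_trigger | plain | minus
    trigger: str | None = None
    trigger_span: tuple[int, int] | None = None
    noise: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# sentence assembly


def _grammar_pools(triggers: Sequence[TriggerEntry], weights: dict[str, float] | None):
    fwd = [e for e in triggers if e.category is TriggerCategory.NEGATION_FORWARD]
    bwd = [e for e in triggers if e.category is TriggerCategory.NEGATION_BACKWARD]
    term = [e for e in triggers if e.category is TriggerCategory.TERMINATION]

    def probs(entries):
        if not entries:
            return None
        w = np.array([(weights or {}).get(e.pattern, 1.0) for e in entries], dtype=float)
        return w / w.sum()

    return (fwd, probs(fwd)), (bwd, probs(bwd)), (term, probs(term))


def _pick(rng: np.random.Generator, items, probs):
    return items[int(rng.choice(len(items), p=probs))]


def _sample_n_sentences(rng: np.random.Generator, mean: float) -> int:
    # 1 + negative binomial keeps the mean exact while staying over-dispersed
    m = max(mean - 1.0, 0.05)
    r = 4.0
    return 1 + int(rng.negative_binomial(r, r / (r + m)))


@dataclass
class _SentencePlan:
    tokens: list[str]
    entity_range: tuple[int, int] | None  # token indices
    label: NegationLabel | None
    mechanism: str
    trigger: str | None
    trigger_range: tuple[int, int] | None  # token indices


def _build_sentence(
    rng: np.random.Generator,
    target_words: int,
    config: GeneratorConfig,
    fillers: list[str],
    terms: list[str],
    modifiers: list[str],
    pools,
) -> _SentencePlan:
    (fwd, fwd_p), (bwd, bwd_p), (term, term_p) = pools

    def some_fillers(k: int) -> list[str]:
        return [fillers[int(i)] for i in rng.integers(0, len(fillers), size=max(k, 0))]

    def a_term() -> list[str]:
        word = terms[int(rng.integers(0, len(terms)))]
        if modifiers and rng.random() < 0.25:
            return [modifiers[int(rng.integers(0, len(modifiers)))], word]
        return [word]

    has_entity = rng.random() < config.entity_rate
    if not has_entity:
        return _SentencePlan(some_fillers(max(target_words, 1)), None, None, "none", None, None)

    negated = rng.random() < config.negation_prevalence
    entity = a_term()
    tokens: list[str]
    if negated:
        use_forward = bool(fwd) and (not bwd or rng.random() < 0.7)
        if use_forward:
            trig = _pick(rng, fwd, fwd_p).pattern.split()
            pre = some_fillers(int(rng.integers(0, 3)))
            gap = some_fillers(int(rng.integers(0, 3)))
            tokens = pre + trig + gap + entity
            trange = (len(pre), len(pre) + len(trig))
            erange = (len(tokens) - len(entity), len(tokens))
            tail = some_fillers(target_words - len(tokens))
            return _SentencePlan(
                tokens + tail, erange, NegationLabel.NEGATED, "forward_trigger",
                " ".join(trig), trange,
            )
        trig = _pick(rng, bwd, bwd_p).pattern.split()
        pre = some_fillers(int(rng.integers(0, 3)))
        gap = some_fillers(int(rng.integers(0, 2)))
        tokens = pre + entity + gap + trig
        erange = (len(pre), len(pre) + len(entity))
        trange = (len(tokens) - len(trig), len(tokens))
        tail = some_fillers(target_words - len(tokens))
        return _SentencePlan(
            tokens + tail, erange, NegationLabel.NEGATED, "backward_trigger",
            " ".join(trig), trange,
        )

    # not negated: plain, or a trigger neutralized by a termination / position
    style = rng.random()
    if style < 0.70 or not fwd:
        pre = some_fillers(int(rng.integers(0, max(target_words - len(entity), 1)) + 1))
        tokens = pre + entity
        erange = (len(pre), len(tokens))
        tail = some_fillers(target_words - len(tokens))
        return _SentencePlan(tokens + tail, erange, NegationLabel.NOT_NEGATED, "plain", None, None)
    if style < 0.85 and term:
        trig = _pick(rng, fwd, fwd_p).pattern.split()
        stop = _pick(rng, term, term_p).pattern.split()
        f1 = some_fillers(1 + int(rng.integers(0, 2)))
        f2 = some_fillers(int(rng.integers(0, 2)))
        tokens = trig + f1 + stop + f2 + entity
        erange = (len(tokens) - len(entity), len(tokens))
        tail = some_fillers(target_words - len(tokens))
        return _SentencePlan(
            tokens + tail, erange, NegationLabel.NOT_NEGATED, "terminated",
            " ".join(trig), (0, len(trig)),
        )
    trig = _pick(rng, fwd, fwd_p).pattern.split()
    pre = some_fillers(int(rng.integers(0, 2)))
    gap = some_fillers(int(rng.integers(0, 2)))
    tokens = pre + entity + gap + trig + some_fillers(1)
    erange = (len(pre), len(pre) + len(entity))
    return _SentencePlan(
        tokens, erange, NegationLabel.NOT_NEGATED, "pre_trigger",
        " ".join(trig), (len(pre) + len(entity) + len(gap), len(pre) + len(entity) + len(gap) + len(trig)),
    )


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[AnnotatedDocument], list[GroundTruthTrace]]:
    """Generate a labeled corpus plus per-entity ground-truth traces.

    Reproducible under ``config.seed``: identical configs give byte-identical
    corpora. Noise rates in ``config.noise`` are applied as a final pass.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    trigger_words = {w.lower() for e in config.triggers for w in e.pattern.split()}
    fillers = [w for w in _read_wordlist("fillers.txt") if w.lower() not in trigger_words]
    terms = [w for w in _read_wordlist("terms.txt") if w.lower() not in trigger_words]
    modifiers = [w for w in ("acute", "chronische", "milde", "ernstige") if w not in trigger_words]
    if len(fillers) < 10 or not terms:
        raise ConfigurationError("word lists too small after removing trigger words")
    pools = _grammar_pools(config.triggers, config.trigger_weights)

    cats = sorted(config.category_mix, key=lambda c: c.value)
    mix = np.array([config.category_mix[c] for c in cats], dtype=float)
    mix = mix / mix.sum()

    docs: list[AnnotatedDocument] = []
    traces: list[GroundTruthTrace] = []
    for d in range(config.n_documents):
        category = cats[int(rng.choice(len(cats), p=mix))]
        profile = config.profiles[category]
        n_sent = _sample_n_sentences(rng, profile.mean_sentences)
        words_per_sentence = profile.mean_words / profile.mean_sentences

        doc_id = f"syn{d:06d}"
        pieces: list[str] = []
        entities: list[EntityAnnotation] = []
        doc_traces: list[GroundTruthTrace] = []
        cursor = 0
        for _s in range(n_sent):
            target = max(1, int(rng.poisson(words_per_sentence)))
            plan = _build_sentence(rng, target, config, fillers, terms, modifiers, pools)
            starts = []
            pos = cursor
            for i, tok in enumerate(plan.tokens):
                starts.append(pos)
                pos += len(tok) + 1  # token + following space (or period slot)
            sent_text = " ".join(plan.tokens) + "."
            pieces.append(sent_text)
            if plan.entity_range is not None:
                lo, hi = plan.entity_range
                estart = starts[lo]
                eend = starts[hi - 1] + len(plan.tokens[hi - 1])
                surface = " ".join(plan.tokens[lo:hi])
                entities.append(
                    EntityAnnotation(estart, eend, surface, gold_label=plan.label)
                )
                tspan = None
                if plan.trigger_range is not None:
                    tlo, thi = plan.trigger_range
                    tspan = (starts[tlo], starts[thi - 1] + len(plan.tokens[thi - 1]))
                doc_traces.append(
                    GroundTruthTrace(
                        doc_id=doc_id,
                        entity_index=-1,  # filled below after sorting
                        label=plan.label,  # type: ignore[arg-type]
                        mechanism=plan.mechanism,
                        trigger=plan.trigger,
                        trigger_span=tspan,
                    )
                )
            cursor += len(sent_text) + 1  # joining space
        text = " ".join(pieces)
        doc = AnnotatedDocument(
            doc_id=doc_id, text=text, category=category, entities=tuple(entities)
        )
        # entities were appended in reading order, which is already sorted
        for ei, tr in enumerate(doc_traces):
            tr.entity_index = ei
        docs.append(doc)
        traces.extend(doc_traces)

    if config.noise.any():
        docs, traces = inject_noise(docs, traces, config.noise, seed=config.seed + 104729)
    return docs, traces


# ---------------------------------------------------------------------------
# noise injection


def _apply_edits(
    doc: AnnotatedDocument, edits: list[tuple[int, int, str]]
) -> AnnotatedDocument:
    """Apply non-overlapping (start, end, replacement) edits and remap entity
    offsets. A boundary shifts by edits strictly before it; insertions at
    exactly an entity boundary do not move it."""
    text = doc.text
    for s, e, rep in sorted(edits, key=lambda t: t[0], reverse=True):
        text = text[:s] + rep + text[e:]

    def shift(b: int) -> int:
        delta = 0
        for s, e, rep in edits:
            if s < b and e <= b:
                delta += len(rep) - (e - s)
        return b + delta

    entities = tuple(
        EntityAnnotation(
            shift(ent.start), shift(ent.end), ent.surface, ent.gold_label, ent.single_term
        )
        for ent in doc.entities
    )
    return AnnotatedDocument(doc.doc_id, text, doc.category, entities)


def inject_noise(
    corpus: Sequence[AnnotatedDocument],
    traces: Sequence[GroundTruthTrace],
    rates: NoiseRates,
    seed: int = 0,
) -> tuple[list[AnnotatedDocument], list[GroundTruthTrace]]:
    """Apply textual noise while keeping entity offsets valid.

    * ``minus``: a trigger-negated entity loses its trigger and gains a
      trailing ``-`` (clinical minus shorthand); its trace mechanism becomes
      ``minus``, the label stays ``negated``.
    * ``missing_whitespace``: spaces outside entity spans are deleted.
    * ``punctuation``: abbreviation-with-period tokens are inserted between
      words, which disturbs naive sentence splitting.
    """
    for name in ("minus", "missing_whitespace", "punctuation"):
        if not (0.0 <= getattr(rates, name) <= 1.0):
            raise ConfigurationError(f"noise rate {name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    trace_map: dict[tuple[str, int], GroundTruthTrace] = {}
    new_traces = [replace(t) for t in traces]
    for t in new_traces:
        trace_map[(t.doc_id, t.entity_index)] = t

    out_docs = []
    for doc in corpus:
        # pass 1: minus shorthand (consumes the trigger span)
        if rates.minus > 0:
            edits: list[tuple[int, int, str]] = []
            for ei, ent in enumerate(doc.entities):
                tr = trace_map.get((doc.doc_id, ei))
                if (
                    tr is None
                    or tr.mechanism not in ("forward_trigger", "backward_trigger")
                    or tr.trigger_span is None
                    or rng.random() >= rates.minus
                ):
                    continue
                ts, te = tr.trigger_span
                if ts > 0 and doc.text[ts - 1] == " ":
                    edits.append((ts - 1, te, ""))
                elif te < len(doc.text) and doc.text[te] == " ":
                    edits.append((ts, te + 1, ""))
                else:
                    edits.append((ts, te, ""))
                edits.append((ent.end, ent.end, "-"))
                tr.mechanism = "minus"
                tr.trigger = None
                tr.trigger_span = None
                tr.noise = tr.noise + ("minus",)
            if edits:
                doc = _apply_edits(doc, edits)

        # pass 2: whitespace deletion
        if rates.missing_whitespace > 0:
            spans = [(e.start, e.end) for e in doc.entities]
            edits = []
            for i, ch in enumerate(doc.text):
                if ch != " ":
                    continue
                if any(s <= i < e for s, e in spans):
                    continue
                if rng.random() < rates.missing_whitespace:
                    edits.append((i, i + 1, ""))
            if edits:
                doc = _apply_edits(doc, edits)

        # pass 3: abbreviation insertions
        if rates.punctuation > 0:
            spans = [(e.start, e.end) for e in doc.entities]
            edits = []
            for i, ch in enumerate(doc.text):
                if ch != " ":
                    continue
                if any(s <= i < e for s, e in spans):
                    continue
                if rng.random() < rates.punctuation:
                    edits.append((i, i + 1, " evt. "))
            if edits:
                doc = _apply_edits(doc, edits)

        out_docs.append(doc)
    return out_docs, new_traces
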