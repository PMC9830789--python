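"""ConText-style rule-based negation detection.

The engine works per sentence. A trigger lexicon holds four kinds of
entries:

* ``negation_forward`` — negates terms *after* the trigger, up to the end of
  the sentence (the default scope) or the nearest termination trigger;
* ``negation_backward`` — negates terms *before* the trigger, back to the
  start of the sentence or the nearest termination trigger;
* ``pseudo`` — phrases that contain a negation trigger but must not be acted
  upon (e.g. "niet alleen" vs the trigger "niet"); pseudo-triggers take
  precedence over the negation triggers they cover;
* ``termination`` — phrases that cut a negation scope short within the
  sentence (e.g. "maar").

A negation entry may carry ``max_scope``, a word count that further limits
the scope; when absent the scope runs to the sentence boundary.

An entity is labeled ``negated`` iff at least one of its tokens lies inside
at least one negation scope. An entity overlapping a trigger's own tokens is
never negated by that trigger (a trigger does not negate itself).

Matching is case-insensitive throughout. Among overlapping candidate
matches the longest wins; ties break on start offset, then category, then
pattern — all deterministic.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

from clinneg.corpus import AnnotatedDocument, ContextPrediction, NegationLabel
from clinneg.errors import ConfigurationError, ValidationError

__all__ = [
    "TriggerCategory",
    "TriggerEntry",
    "TriggerLexicon",
    "TriggerMatch",
    "SentenceSpan",
    "Scope",
    "tokenize",
    "split_sentences",
    "compile_lexicon",
    "find_trigger_matches",
    "compute_scope",
    "classify_entities_rule",
    "insert_whitespace",
]

# A token is a maximal run of word characters, optionally keeping a trailing
# hyphen attached (clinical minus shorthand, "nausea-"), or a single
# non-word non-space character.
TOKEN_RE = re.compile(r"\w+-(?!\w)|\w+|[^\w\s]", re.UNICODE)

_SENT_FINAL = ".!?"


class TriggerCategory(str, enum.Enum):
    NEGATION_FORWARD = "negation_forward"
    NEGATION_BACKWARD = "negation_backward"
    PSEUDO = "pseudo"
    TERMINATION = "termination"


_NEGATION_CATEGORIES = (TriggerCategory.NEGATION_FORWARD, TriggerCategory.NEGATION_BACKWARD)


@dataclass(frozen=True)
class TriggerEntry:
    """One lexicon entry: a literal phrase or regular expression."""

    pattern: str
    category: TriggerCategory
    max_scope: int | None = None

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ConfigurationError("trigger pattern must be non-empty")
        if self.max_scope is not None:
            if self.max_scope < 1:
                raise ConfigurationError(
                    f"max_scope must be >= 1, got {self.max_scope} for {self.pattern!r}"
                )
            if self.category not in _NEGATION_CATEGORIES:
                raise ConfigurationError(
                    f"max_scope only applies to negation triggers, not {self.category.value} "
                    f"({self.pattern!r})"
                )


def _compile_pattern(pattern: str) -> re.Pattern:
    # Wrap with word-boundary lookarounds when the pattern starts/ends with a
    # word character, so "niet" never matches inside "nieteen".
    prefix = r"(?<!\w)" if re.match(r"\w", pattern) else ""
    suffix = r"(?!\w)" if re.search(r"\w\Z", pattern) else ""
    try:
        return re.compile(f"{prefix}(?:{pattern}){suffix}", re.IGNORECASE | re.UNICODE)
    except re.error as exc:
        raise ConfigurationError(f"invalid trigger regex {pattern!r}: {exc}") from exc


@dataclass(frozen=True)
class TriggerLexicon:
    """Compiled trigger lexicon; matching is case-insensitive."""

    entries: tuple[TriggerEntry, ...]
    _compiled: tuple[re.Pattern, ...]

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TriggerLexicon":
        """Read a UTF-8 TSV lexicon: columns ``pattern``, ``category``,
        ``max_scope`` (empty = sentence default); ``#`` starts a comment."""
        entries = []
        for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = line.rstrip()
            if not line or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ConfigurationError(f"{path}:{lineno}: expected at least 2 columns")
            pattern, category = fields[0], fields[1]
            max_scope = None
            if len(fields) >= 3 and fields[2].strip():
                max_scope = int(fields[2])
            entries.append(TriggerEntry(pattern, TriggerCategory(category), max_scope))
        return compile_lexicon(entries)

    @classmethod
    def default(cls) -> "TriggerLexicon":
        """The packaged illustrative Dutch lexicon."""
        ref = resources.files("clinneg").joinpath("lexicons/dutch_default.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


def compile_lexicon(entries: Sequence[TriggerEntry]) -> TriggerLexicon:
    """Compile entries into a lexicon.

    Rejects an empty entry list, duplicate (pattern, category) pairs and
    invalid regexes (naming the offending pattern).
    """
    if not entries:
        raise ConfigurationError("trigger lexicon must contain at least one entry")
    seen: set[tuple[str, TriggerCategory]] = set()
    for entry in entries:
        key = (entry.pattern.lower(), entry.category)
        if key in seen:
            raise ConfigurationError(
                f"duplicate trigger entry: {entry.pattern!r} ({entry.category.value})"
            )
        seen.add(key)
    compiled = tuple(_compile_pattern(e.pattern) for e in entries)
    return TriggerLexicon(entries=tuple(entries), _compiled=compiled)


# ---------------------------------------------------------------------------
# tokenization and sentence splitting


@dataclass(frozen=True)
class SentenceSpan:
    """One sentence: its character span and the spans of its tokens."""

    start: int
    end: int
    tokens: tuple[tuple[int, int], ...]

    def token_texts(self, text: str) -> list[str]:
        return [text[s:e] for s, e in self.tokens]


def tokenize(text: str, offset: int = 0) -> list[tuple[int, int]]:
    """Token character spans of ``text``, shifted by ``offset``."""
    return [(m.start() + offset, m.end() + offset) for m in TOKEN_RE.finditer(text)]


def _default_boundaries(text: str) -> list[int]:
    """Sentence break positions: after runs of sentence-final punctuation
    followed by whitespace/end-of-text, and after newlines."""
    points = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c in _SENT_FINAL:
            j = i + 1
            while j < n and text[j] in _SENT_FINAL:
                j += 1
            if j >= n or text[j].isspace():
                points.append(j)
            i = j
        elif c == "\n":
            points.append(i + 1)
            i += 1
        else:
            i += 1
    return points


Splitter = Callable[[str], list[SentenceSpan]]


def split_sentences(text: str, splitter: Splitter | None = None) -> list[SentenceSpan]:
    """Split ``text`` into sentence spans.

    The default splitter breaks after sentence-final punctuation (``. ! ?``
    followed by whitespace) and at newlines. A custom ``splitter`` callable
    can be injected (e.g. a model-based splitter); it must return
    :class:`SentenceSpan` objects over the same text.
    """
    if splitter is not None:
        return splitter(text)
    if not text:
        return []
    sentences = []
    prev = 0
    for point in _default_boundaries(text) + [len(text)]:
        if point <= prev:
            continue
        segment = text[prev:point]
        toks = tokenize(segment, offset=prev)
        if toks:
            sentences.append(SentenceSpan(start=toks[0][0], end=toks[-1][1], tokens=tuple(toks)))
        prev = point
    return sentences


# ---------------------------------------------------------------------------
# trigger matching


@dataclass(frozen=True)
class TriggerMatch:
    """A lexicon entry matched inside one sentence."""

    entry: TriggerEntry
    token_start: int  # sentence-local token index, inclusive
    token_end: int  # exclusive
    char_start: int
    char_end: int


def _char_to_token_range(sentence: SentenceSpan, start: int, end: int) -> tuple[int, int] | None:
    """Sentence-local indices of tokens overlapping [start, end), or None."""
    idxs = [i for i, (ts, te) in enumerate(sentence.tokens) if ts < end and te > start]
    if not idxs:
        return None
    return idxs[0], idxs[-1] + 1


def find_trigger_matches(
    sentence: SentenceSpan, text: str, lexicon: TriggerLexicon
) -> list[TriggerMatch]:
    """All resolved trigger matches within one sentence.

    Resolution order: (1) negation matches fully contained in a pseudo match
    span are removed (pseudo precedence); (2) overlapping candidates are
    resolved greedily, longest first.
    """
    candidates: list[TriggerMatch] = []
    for entry, rx in zip(lexicon.entries, lexicon._compiled):
        for m in rx.finditer(text, sentence.start, sentence.end):
            trange = _char_to_token_range(sentence, m.start(), m.end())
            if trange is None:
                continue
            candidates.append(TriggerMatch(entry, trange[0], trange[1], m.start(), m.end()))

    pseudo_spans = [
        (c.char_start, c.char_end) for c in candidates if c.entry.category is TriggerCategory.PSEUDO
    ]
    candidates = [
        c
        for c in candidates
        if not (
            c.entry.category in _NEGATION_CATEGORIES
            and any(ps <= c.char_start and c.char_end <= pe for ps, pe in pseudo_spans)
        )
    ]

    order = sorted(
        candidates,
        key=lambda c: (
            -(c.char_end - c.char_start),
            c.char_start,
            c.entry.category.value,
            c.entry.pattern,
        ),
    )
    kept: list[TriggerMatch] = []
    for cand in order:
        if all(cand.char_end <= k.char_start or cand.char_start >= k.char_end for k in kept):
            kept.append(cand)
    kept.sort(key=lambda c: c.char_start)
    return kept


# ---------------------------------------------------------------------------
# scope computation


@dataclass(frozen=True)
class Scope:
    """Token range (sentence-local, half-open) a negation applies to."""

    direction: str  # "forward" | "backward"
    token_start: int
    token_end: int

    def covers(self, token_index: int) -> bool:
        return self.token_start <= token_index < self.token_end


def compute_scope(
    match: TriggerMatch, sentence: SentenceSpan, terminations: Sequence[TriggerMatch]
) -> Scope:
    """Scope of one negation trigger match.

    Forward scope: tokens after the trigger up to the sentence end; backward
    scope: tokens before the trigger from the sentence start. The scope is
    truncated at the nearest termination match in the scope direction
    (termination tokens excluded) and, when the entry defines ``max_scope``,
    to that many words.
    """
    if match.entry.category not in _NEGATION_CATEGORIES:
        raise ValidationError(
            f"compute_scope requires a negation trigger, got {match.entry.category.value}"
        )
    n = len(sentence.tokens)
    if match.entry.category is TriggerCategory.NEGATION_FORWARD:
        start, end = match.token_end, n
        for term in terminations:
            if term.token_start >= start:
                end = min(end, term.token_start)
        if match.entry.max_scope is not None:
            end = min(end, start + match.entry.max_scope)
        return Scope("forward", start, max(start, end))
    start, end = 0, match.token_start
    for term in terminations:
        if term.token_end <= end:
            start = max(start, term.token_end)
    if match.entry.max_scope is not None:
        start = max(start, end - match.entry.max_scope)
    return Scope("backward", min(start, end), end)


# ---------------------------------------------------------------------------
# optional preprocessing


def insert_whitespace(text: str) -> tuple[str, list[int]]:
    """Insert spaces around parentheses and between concatenated punctuation
    and word characters. Returns the new text and a position map ``pos`` such
    that offset ``i`` in the original text maps to ``pos[i]`` in the result
    (``pos`` has length ``len(text) + 1``).
    """
    out: list[str] = []
    pos: list[int] = []
    prev = ""
    for ch in text:
        if prev and not prev.isspace() and not ch.isspace():
            breaking = (
                ch in "()"
                or prev in "()"
                or (prev.isalnum() and not ch.isalnum() and ch not in "-.,")
                or (not prev.isalnum() and prev not in "-" and ch.isalnum() and prev not in ".,")
            )
            if breaking:
                out.append(" ")
        pos.append(len(out))
        out.append(ch)
        prev = ch
    pos.append(len(out))
    return "".join(out), pos


# ---------------------------------------------------------------------------
# entity classification


def _entity_sentence_tokens(
    sentences: Sequence[SentenceSpan], start: int, end: int
) -> tuple[int, list[int]] | None:
    """Locate the sentence holding the entity's first token; return the
    sentence index and the sentence-local indices of all entity tokens in
    that sentence. An entity spanning a sentence boundary (possible under
    bad splitting) belongs to the sentence of its first token."""
    for si, sent in enumerate(sentences):
        idxs = [i for i, (ts, te) in enumerate(sent.tokens) if ts < end and te > start]
        if idxs:
            return si, idxs
    return None


def classify_entities_rule(
    doc: AnnotatedDocument,
    lexicon: TriggerLexicon,
    splitter: Splitter | None = None,
    preprocess: bool = False,
) -> list[ContextPrediction]:
    """Label every entity of ``doc`` with the rule engine.

    An entity is ``negated`` iff at least one of its tokens lies inside at
    least one negation scope in its sentence (logical OR over scopes); an
    entity overlapping a trigger's own tokens is not negated by that
    trigger. Predictions carry ``method="rule"`` and no probability.

    ``preprocess=True`` runs the whitespace-insertion pass first; entity
    offsets are remapped onto the transformed text.
    """
    text = doc.text
    ent_spans = [(e.start, e.end) for e in doc.entities]
    if preprocess:
        text, pos = insert_whitespace(text)
        ent_spans = [(pos[s], pos[e - 1] + 1) for s, e in ent_spans]

    sentences = split_sentences(text, splitter)
    per_sentence: list[tuple[list[tuple[TriggerMatch, Scope]], SentenceSpan]] = []
    for sent in sentences:
        matches = find_trigger_matches(sent, text, lexicon)
        terminations = [m for m in matches if m.entry.category is TriggerCategory.TERMINATION]
        scoped = [
            (m, compute_scope(m, sent, terminations))
            for m in matches
            if m.entry.category in _NEGATION_CATEGORIES
        ]
        per_sentence.append((scoped, sent))

    predictions = []
    for ei, (estart, eend) in enumerate(ent_spans):
        label = NegationLabel.NOT_NEGATED
        located = _entity_sentence_tokens(sentences, estart, eend)
        if located is not None:
            si, ent_token_idxs = located
            ent_tokens = set(ent_token_idxs)
            for match, scope in per_sentence[si][0]:
                if ent_tokens & set(range(match.token_start, match.token_end)):
                    continue  # a trigger does not negate itself
                if any(scope.covers(ti) for ti in ent_token_idxs):
                    label = NegationLabel.NEGATED
                    break
        predictions.append(
            ContextPrediction(doc_id=doc.doc_id, entity_index=ei, label=label, method="rule")
        )
    return predictions
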