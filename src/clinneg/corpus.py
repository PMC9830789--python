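"""Domain types for clinical records and standoff-annotation I/O.

A corpus is a collection of :class:`AnnotatedDocument`: one clinical record
with its free text, a record category and an ordered list of entity
annotations (character spans of medical terms, optionally carrying a gold
negation label).

Two on-disk dialects are supported:

* **jsonl** (native): one JSON object per line with keys ``doc_id``,
  ``category``, ``text`` and ``entities`` (each entity: ``start``, ``end``,
  ``surface``, optional ``gold_label``, optional ``single_term``).
* **brat**: a directory of ``<name>.txt`` / ``<name>.ann`` pairs. ``.ann``
  lines are tab-separated ``T<id>\tTERM <start> <end>\t<surface>`` plus
  optional attribute lines ``A<id>\tNegated T<n>`` and an optional comment
  line ``# category: <record category>``.

Character offsets are 0-based with half-open ends. Text is taken verbatim
(no unicode normalization) so offsets stay valid.
"""

from __future__ import annotations

import enum
import json
import os
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from clinneg.errors import CorpusIOError, ValidationError

__all__ = [
    "RecordCategory",
    "NegationLabel",
    "EntityAnnotation",
    "AnnotatedDocument",
    "ContextPrediction",
    "LoadFailure",
    "CorpusLoadResult",
    "load_corpus",
    "save_corpus",
    "filter_corpus",
    "load_predictions",
    "save_predictions",
]


class RecordCategory(str, enum.Enum):
    """The four clinical record categories."""

    GENERAL_PRACTITIONER = "general_practitioner"
    SPECIALIST_LETTER = "specialist_letter"
    RADIOLOGY_REPORT = "radiology_report"
    DISCHARGE_LETTER = "discharge_letter"


class NegationLabel(str, enum.Enum):
    """Binary context label for one annotated medical term."""

    NEGATED = "negated"
    NOT_NEGATED = "not_negated"


@dataclass(frozen=True)
class EntityAnnotation:
    """One annotated medical term: a character span of the document text.

    ``single_term`` marks whether the span corresponds to exactly one medical
    term; corpus filtering excludes documents where it is False.
    """

    start: int
    end: int
    surface: str
    gold_label: NegationLabel | None = None
    single_term: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"entity span must satisfy 0 <= start < end, got [{self.start}, {self.end})"
            )

    def validate_against(self, text: str, doc_id: str | None = None) -> None:
        """Check that the span lies inside ``text`` and matches ``surface``."""
        if self.end > len(text):
            raise ValidationError(
                f"entity span [{self.start}, {self.end}) exceeds text length {len(text)}",
                doc_id=doc_id,
            )
        actual = text[self.start : self.end]
        if actual != self.surface:
            raise ValidationError(
                f"entity surface {self.surface!r} does not match text slice {actual!r} "
                f"at [{self.start}, {self.end})",
                doc_id=doc_id,
            )


@dataclass(frozen=True)
class AnnotatedDocument:
    """One clinical record with its entity annotations.

    Entities are stored sorted by start offset; construction validates every
    span against the text.
    """

    doc_id: str
    text: str
    category: RecordCategory
    entities: tuple[EntityAnnotation, ...] = ()

    def __post_init__(self) -> None:
        ents = tuple(sorted(self.entities, key=lambda e: (e.start, e.end)))
        object.__setattr__(self, "entities", ents)
        for ent in ents:
            ent.validate_against(self.text, doc_id=self.doc_id)

    def with_gold_labels(self, labels: Sequence[NegationLabel]) -> "AnnotatedDocument":
        if len(labels) != len(self.entities):
            raise ValidationError(
                f"expected {len(self.entities)} labels, got {len(labels)}", doc_id=self.doc_id
            )
        ents = tuple(replace(e, gold_label=lab) for e, lab in zip(self.entities, labels))
        return replace(self, entities=ents)


@dataclass(frozen=True)
class ContextPrediction:
    """Per-entity output of one detection method."""

    doc_id: str
    entity_index: int
    label: NegationLabel
    probability: float | None = None
    method: str = "unknown"

    def __post_init__(self) -> None:
        if self.probability is not None and not (0.0 <= self.probability <= 1.0):
            raise ValidationError(
                f"probability {self.probability} outside [0, 1]", doc_id=self.doc_id
            )

    @classmethod
    def from_probability(
        cls,
        doc_id: str,
        entity_index: int,
        probability: float,
        method: str,
        threshold: float = 0.5,
    ) -> "ContextPrediction":
        """Build a prediction whose label follows the decision threshold.

        The label is ``negated`` iff ``probability >= threshold``.
        """
        label = NegationLabel.NEGATED if probability >= threshold else NegationLabel.NOT_NEGATED
        return cls(doc_id, entity_index, label, float(probability), method)


@dataclass(frozen=True)
class LoadFailure:
    """One record that could not be parsed."""

    doc_id: str
    reason: str


@dataclass
class CorpusLoadResult:
    documents: list[AnnotatedDocument]
    failures: list[LoadFailure] = field(default_factory=list)


# ---------------------------------------------------------------------------
# jsonl dialect


def _entity_to_json(ent: EntityAnnotation) -> dict:
    d: dict = {"start": ent.start, "end": ent.end, "surface": ent.surface}
    if ent.gold_label is not None:
        d["gold_label"] = ent.gold_label.value
    if not ent.single_term:
        d["single_term"] = False
    return d


def _entity_from_json(d: dict) -> EntityAnnotation:
    label = d.get("gold_label")
    return EntityAnnotation(
        start=int(d["start"]),
        end=int(d["end"]),
        surface=str(d["surface"]),
        gold_label=NegationLabel(label) if label is not None else None,
        single_term=bool(d.get("single_term", True)),
    )


def _doc_to_json(doc: AnnotatedDocument) -> dict:
    return {
        "doc_id": doc.doc_id,
        "category": doc.category.value,
        "text": doc.text,
        "entities": [_entity_to_json(e) for e in doc.entities],
    }


def _doc_from_json(d: dict) -> AnnotatedDocument:
    return AnnotatedDocument(
        doc_id=str(d["doc_id"]),
        text=str(d["text"]),
        category=RecordCategory(d["category"]),
        entities=tuple(_entity_from_json(e) for e in d.get("entities", [])),
    )


def _load_jsonl(path: Path, on_error: str) -> CorpusLoadResult:
    result = CorpusLoadResult(documents=[])
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            doc_id = f"{path.name}:{lineno}"
            try:
                raw = json.loads(line)
                doc_id = str(raw.get("doc_id", doc_id))
                result.documents.append(_doc_from_json(raw))
            except (json.JSONDecodeError, KeyError, ValueError, ValidationError) as exc:
                if on_error == "raise":
                    raise ValidationError(f"line {lineno}: {exc}", doc_id=doc_id) from exc
                result.failures.append(LoadFailure(doc_id=doc_id, reason=str(exc)))
    return result


# ---------------------------------------------------------------------------
# brat dialect


def _load_brat_pair(txt_path: Path) -> AnnotatedDocument:
    ann_path = txt_path.with_suffix(".ann")
    if not ann_path.exists():
        raise CorpusIOError(f"missing annotation file: {ann_path}")
    text = txt_path.read_text(encoding="utf-8")
    category = RecordCategory.GENERAL_PRACTITIONER
    spans: dict[str, EntityAnnotation] = {}
    negated_ids: set[str] = set()
    labeled_ids: set[str] = set()
    for line in ann_path.read_text(encoding="utf-8").splitlines():
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("category:"):
                category = RecordCategory(body.split(":", 1)[1].strip())
            continue
        fields = line.split("\t")
        if line.startswith("T"):
            if len(fields) < 3:
                raise ValidationError(f"malformed span line: {line!r}", doc_id=txt_path.stem)
            tid = fields[0]
            _type, start_s, end_s = fields[1].split()
            spans[tid] = EntityAnnotation(int(start_s), int(end_s), fields[2])
        elif line.startswith("A"):
            # attribute line: "A1\t<Negated|NotNegated> T1"
            attr, tid = fields[1].split()
            labeled_ids.add(tid)
            if attr.lower() == "negated":
                negated_ids.add(tid)
    entities = []
    for tid, ent in spans.items():
        label: NegationLabel | None = None
        if tid in labeled_ids:
            label = NegationLabel.NEGATED if tid in negated_ids else NegationLabel.NOT_NEGATED
        entities.append(replace(ent, gold_label=label))
    return AnnotatedDocument(
        doc_id=txt_path.stem, text=text, category=category, entities=tuple(entities)
    )


def _load_brat(path: Path, on_error: str) -> CorpusLoadResult:
    result = CorpusLoadResult(documents=[])
    txt_files = sorted(path.glob("*.txt"))
    if not txt_files:
        raise CorpusIOError(f"no .txt files found in brat directory: {path}")
    for txt_path in txt_files:
        try:
            result.documents.append(_load_brat_pair(txt_path))
        except (ValidationError, ValueError) as exc:
            if on_error == "raise":
                raise
            result.failures.append(LoadFailure(doc_id=txt_path.stem, reason=str(exc)))
    return result


# ---------------------------------------------------------------------------
# public API


def load_corpus(
    path: str | os.PathLike, format: str = "jsonl", on_error: str = "raise"
) -> CorpusLoadResult:
    """Load a corpus from ``path``.

    Parameters
    ----------
    path:
        A jsonl file or a brat directory, depending on ``format``.
    format:
        ``"jsonl"`` or ``"brat"``.
    on_error:
        ``"raise"`` (default) raises on the first malformed record;
        ``"report"`` collects malformed records in ``failures`` so they can
        be counted by :func:`filter_corpus` instead of being silently dropped.
    """
    p = Path(path)
    if not p.exists():
        raise CorpusIOError(f"corpus path does not exist: {p}")
    if on_error not in ("raise", "report"):
        raise ValueError(f"on_error must be 'raise' or 'report', got {on_error!r}")
    if format == "jsonl":
        return _load_jsonl(p, on_error)
    if format == "brat":
        return _load_brat(p, on_error)
    raise ValueError(f"unsupported corpus format: {format!r}")


def _atomic_write(path: Path, content: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=str(path.parent), prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(content)
        os.replace(tmp, path)
    except OSError as exc:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise CorpusIOError(f"cannot write {path}: {exc}") from exc


def save_corpus(
    docs: Iterable[AnnotatedDocument], path: str | os.PathLike, format: str = "jsonl"
) -> None:
    """Write ``docs`` to ``path``. Deterministic: identical input gives
    byte-identical output. jsonl writes are atomic."""
    p = Path(path)
    docs = list(docs)
    if format == "jsonl":
        lines = [
            json.dumps(_doc_to_json(d), ensure_ascii=False, sort_keys=True, separators=(",", ":"))
            for d in docs
        ]
        _atomic_write(p, "".join(line + "\n" for line in lines))
    elif format == "brat":
        p.mkdir(parents=True, exist_ok=True)
        for doc in docs:
            (p / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
            lines = [f"# category: {doc.category.value}"]
            for i, ent in enumerate(doc.entities, start=1):
                lines.append(f"T{i}\tTERM {ent.start} {ent.end}\t{ent.surface}")
            attr = 1
            for i, ent in enumerate(doc.entities, start=1):
                if ent.gold_label is not None:
                    name = "Negated" if ent.gold_label is NegationLabel.NEGATED else "NotNegated"
                    lines.append(f"A{attr}\t{name} T{i}")
                    attr += 1
            (p / f"{doc.doc_id}.ann").write_text(
                "".join(line + "\n" for line in lines), encoding="utf-8"
            )
    else:
        raise ValueError(f"unsupported corpus format: {format!r}")


def filter_corpus(
    docs: Sequence[AnnotatedDocument], failures: Sequence[LoadFailure] = ()
) -> tuple[list[AnnotatedDocument], dict[str, int]]:
    """Apply record-exclusion rules and return ``(kept, exclusion_log)``.

    Excluded are: documents with zero annotations (``no_annotation``),
    documents that failed parsing (``corrupted``, passed in as ``failures``),
    and documents containing an annotation that does not correspond to a
    single medical term (``not_single_term``: flagged entities or
    whitespace-only surfaces).

    Conservation: ``len(kept) + sum(log.values()) == len(docs) + len(failures)``.
    """
    kept: list[AnnotatedDocument] = []
    log: dict[str, int] = {}

    def bump(reason: str) -> None:
        log[reason] = log.get(reason, 0) + 1

    for _ in failures:
        bump("corrupted")
    for doc in docs:
        if not doc.entities:
            bump("no_annotation")
        elif any((not e.single_term) or (not e.surface.strip()) for e in doc.entities):
            bump("not_single_term")
        else:
            kept.append(doc)
    return kept, log


# ---------------------------------------------------------------------------
# predictions I/O (shared jsonl schema)


def save_predictions(preds: Iterable[ContextPrediction], path: str | os.PathLike) -> None:
    """Write predictions as one JSON object per line."""
    lines = []
    for p in preds:
        d: dict = {
            "doc_id": p.doc_id,
            "entity_index": p.entity_index,
            "label": p.label.value,
            "method": p.method,
        }
        if p.probability is not None:
            d["probability"] = p.probability
        lines.append(json.dumps(d, ensure_ascii=False, sort_keys=True, separators=(",", ":")))
    _atomic_write(Path(path), "".join(line + "\n" for line in lines))


def load_predictions(path: str | os.PathLike) -> list[ContextPrediction]:
    p = Path(path)
    if not p.exists():
        raise CorpusIOError(f"predictions file does not exist: {p}")
    preds = []
    with p.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            preds.append(
                ContextPrediction(
                    doc_id=str(d["doc_id"]),
                    entity_index=int(d["entity_index"]),
                    label=NegationLabel(d["label"]),
                    probability=d.get("probability"),
                    method=str(d.get("method", "unknown")),
                )
            )
    return preds
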