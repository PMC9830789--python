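"""Ensembling, cross-validation folds, metrics and error analysis.

Positive class throughout is ``negated``. Undefined ratios (zero
denominators) are reported as ``None`` rather than 0, so averages are never
silently inflated.
"""

from __future__ import annotations

import enum
from collections import Counter
from itertools import combinations
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from clinneg.corpus import (
    AnnotatedDocument,
    ContextPrediction,
    NegationLabel,
    RecordCategory,
)
from clinneg.errors import ConfigurationError, ValidationError

__all__ = [
    "CVConfig",
    "MetricsReport",
    "ErrorCategory",
    "ErrorRecord",
    "KappaResult",
    "make_folds",
    "majority_vote",
    "ensemble_predictions",
    "compute_metrics",
    "metrics_to_frame",
    "error_intersections",
    "cohens_kappa",
    "error_report",
]


# ---------------------------------------------------------------------------
# folds


@dataclass(frozen=True)
class CVConfig:
    """Shared-fold cross-validation settings.

    ``grouping="entity"`` assigns items independently (fold sizes differ by
    at most one); ``grouping="record"`` keeps all items of one record in the
    same fold (sizes then balanced greedily).
    """

    k: int = 10
    seed: int = 0
    grouping: str = "record"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ConfigurationError(f"k must be >= 2, got {self.k}")
        if self.grouping not in ("entity", "record"):
            raise ConfigurationError(f"grouping must be 'entity' or 'record', got {self.grouping!r}")


def make_folds(
    n_items: int, config: CVConfig, groups: Sequence[Hashable] | None = None
) -> np.ndarray:
    """Deterministic fold assignment: an array of fold ids, one per item.

    Without groups (or with ``grouping="entity"``) items are shuffled under
    the seed and dealt round-robin, so fold sizes differ by at most one.
    With ``grouping="record"``, ``groups[i]`` is item *i*'s record key and
    whole records are dealt to the currently smallest fold.
    """
    if n_items < config.k:
        raise ConfigurationError(f"{n_items} items cannot fill {config.k} folds")
    rng = np.random.default_rng(config.seed)
    assignment = np.empty(n_items, dtype=np.int64)
    if config.grouping == "entity" or groups is None:
        order = rng.permutation(n_items)
        for pos, item in enumerate(order):
            assignment[item] = pos % config.k
        return assignment
    if len(groups) != n_items:
        raise ValidationError(f"expected {n_items} group keys, got {len(groups)}")
    by_group: dict[Hashable, list[int]] = {}
    for i, g in enumerate(groups):
        by_group.setdefault(g, []).append(i)
    keys = sorted(by_group, key=str)
    order = rng.permutation(len(keys))
    sizes = np.zeros(config.k, dtype=np.int64)
    for gi in order:
        members = by_group[keys[gi]]
        fold = int(np.argmin(sizes))
        sizes[fold] += len(members)
        for i in members:
            assignment[i] = fold
    return assignment


# ---------------------------------------------------------------------------
# ensemble


def majority_vote(predictions: Sequence[ContextPrediction]) -> ContextPrediction:
    """Majority vote over exactly three hard labels for one entity.

    The resulting label is the one predicted by at least two of the three
    classifiers; the prediction carries ``method="ensemble"`` and no
    probability.
    """
    if len(predictions) != 3:
        ident = {(p.doc_id, p.entity_index) for p in predictions}
        raise ValidationError(f"majority vote needs exactly 3 predictions, got {len(predictions)} for {sorted(ident)}")
    keys = {(p.doc_id, p.entity_index) for p in predictions}
    if len(keys) != 1:
        raise ValidationError(f"majority vote got predictions for different entities: {sorted(keys)}")
    doc_id, entity_index = next(iter(keys))
    votes = sum(1 for p in predictions if p.label is NegationLabel.NEGATED)
    label = NegationLabel.NEGATED if votes >= 2 else NegationLabel.NOT_NEGATED
    return ContextPrediction(doc_id=doc_id, entity_index=entity_index, label=label, method="ensemble")


def ensemble_predictions(
    per_method: Sequence[Sequence[ContextPrediction]],
) -> list[ContextPrediction]:
    """Entity-wise majority vote over three aligned prediction lists."""
    if len(per_method) != 3:
        raise ValidationError(f"ensemble requires exactly 3 prediction sets, got {len(per_method)}")
    maps = []
    for preds in per_method:
        m = {(p.doc_id, p.entity_index): p for p in preds}
        if len(m) != len(preds):
            raise ValidationError("duplicate predictions for the same entity")
        maps.append(m)
    keys = set(maps[0])
    for m in maps[1:]:
        if set(m) != keys:
            missing = sorted((keys ^ set(m)))[:3]
            raise ValidationError(f"prediction sets cover different entities, e.g. {missing}")
    return [majority_vote([m[k] for m in maps]) for k in sorted(keys)]


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and derived scores for the ``negated`` class."""

    stratum: str
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float | None
    recall: float | None
    f1: float | None

    @classmethod
    def from_counts(cls, stratum: str, tp: int, fp: int, fn: int, tn: int) -> "MetricsReport":
        precision = tp / (tp + fp) if (tp + fp) > 0 else None
        recall = tp / (tp + fn) if (tp + fn) > 0 else None
        if precision is None or recall is None:
            f1 = None
        elif precision + recall == 0:
            f1 = 0.0
        else:
            f1 = 2 * precision * recall / (precision + recall)
        return cls(stratum, tp, fp, fn, tn, precision, recall, f1)


def _gold_map(
    gold_docs: Iterable[AnnotatedDocument],
) -> dict[tuple[str, int], tuple[NegationLabel, RecordCategory]]:
    out = {}
    for doc in gold_docs:
        for ei, ent in enumerate(doc.entities):
            if ent.gold_label is not None:
                out[(doc.doc_id, ei)] = (ent.gold_label, doc.category)
    return out


def compute_metrics(
    predictions: Sequence[ContextPrediction],
    gold_docs: Sequence[AnnotatedDocument],
    stratify_by_category: bool = True,
) -> list[MetricsReport]:
    """Precision/recall/F1 for the ``negated`` class, overall and per category.

    Predictions must cover every gold-labeled entity exactly once; a
    prediction for an entity without a gold label is a validation error.
    """
    gold = _gold_map(gold_docs)
    seen: set[tuple[str, int]] = set()
    counts: dict[str, list[int]] = {}  # stratum -> [tp, fp, fn, tn]

    def bump(stratum: str, slot: int) -> None:
        counts.setdefault(stratum, [0, 0, 0, 0])[slot] += 1

    for pred in predictions:
        key = (pred.doc_id, pred.entity_index)
        if key not in gold:
            raise ValidationError(
                f"prediction for entity {pred.entity_index} has no gold label",
                doc_id=pred.doc_id,
            )
        if key in seen:
            raise ValidationError(
                f"duplicate prediction for entity {pred.entity_index}", doc_id=pred.doc_id
            )
        seen.add(key)
        gold_label, category = gold[key]
        predicted_neg = pred.label is NegationLabel.NEGATED
        actually_neg = gold_label is NegationLabel.NEGATED
        slot = (
            0 if (predicted_neg and actually_neg)
            else 1 if predicted_neg
            else 2 if actually_neg
            else 3
        )
        bump("all", slot)
        if stratify_by_category:
            bump(category.value, slot)

    missing = set(gold) - seen
    if missing:
        doc_id, ei = sorted(missing)[0]
        raise ValidationError(
            f"no prediction for gold-labeled entity {ei} (and {len(missing) - 1} more)",
            doc_id=doc_id,
        )

    strata = ["all"] + sorted(s for s in counts if s != "all")
    return [MetricsReport.from_counts(s, *counts[s]) for s in strata]


def metrics_to_frame(reports: Mapping[str, Sequence[MetricsReport]]) -> pd.DataFrame:
    """Tabulate per-method metric reports: columns category, method,
    precision, recall, f1 (plus raw counts)."""
    rows = []
    for method, reps in reports.items():
        for r in reps:
            rows.append(
                {
                    "category": r.stratum,
                    "method": method,
                    "precision": r.precision,
                    "recall": r.recall,
                    "f1": r.f1,
                    "tp": r.tp,
                    "fp": r.fp,
                    "fn": r.fn,
                    "tn": r.tn,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# error analysis


class ErrorCategory(str, enum.Enum):
    """The ten-way error taxonomy used for manual error annotation."""

    UNCOMMON_NEGATION = "uncommon_negation"
    MINUS = "minus"
    SCOPE = "scope"
    PUNCTUATION = "punctuation"
    NEGATION_OF_DIFFERENT_TERM = "negation_of_different_term"
    WRONG_MODALITY = "wrong_modality"
    SPECULATION = "speculation"
    AMBIGUITY = "ambiguity"
    OTHER = "other"
    ANNOTATION_ERROR = "annotation_error"


@dataclass(frozen=True)
class ErrorRecord:
    doc_id: str
    entity_index: int
    polarity: str  # "false_positive" | "false_negative"
    methods: frozenset[str]
    category: ErrorCategory | None = None


@dataclass(frozen=True)
class KappaResult:
    p_observed: float
    p_expected: float
    kappa: float | None  # None when expected agreement is 1


def cohens_kappa(labels_a: Sequence[Hashable], labels_b: Sequence[Hashable]) -> KappaResult:
    """Chance-corrected agreement between two categorical annotators.

    ``p_o`` is the fraction of equal labels; ``p_e`` the sum over categories
    of the two annotators' marginal products; kappa = (p_o - p_e)/(1 - p_e),
    reported as ``None`` when ``p_e`` equals 1.
    """
    if len(labels_a) != len(labels_b):
        raise ValidationError(
            f"annotator vectors differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    if not labels_a:
        raise ValidationError("annotator vectors are empty")
    n = len(labels_a)
    p_o = sum(1 for a, b in zip(labels_a, labels_b) if a == b) / n
    ca, cb = Counter(labels_a), Counter(labels_b)
    p_e = sum((ca[c] / n) * (cb[c] / n) for c in set(ca) | set(cb))
    if p_e >= 1.0:
        return KappaResult(p_o, p_e, None)
    return KappaResult(p_o, p_e, (p_o - p_e) / (1.0 - p_e))


def error_intersections(
    error_sets: Mapping[str, set[Hashable]],
) -> dict[frozenset[str], int]:
    """Exclusive counts per non-empty method subset.

    Each erred-on entity is counted in exactly the subset of methods that
    erred on it; counts over all subsets sum to the size of the union.
    """
    methods = sorted(error_sets)
    universe = set().union(*error_sets.values()) if error_sets else set()
    counts: dict[frozenset[str], int] = {}
    for r in range(1, len(methods) + 1):
        for combo in combinations(methods, r):
            counts[frozenset(combo)] = 0
    for item in universe:
        who = frozenset(m for m in methods if item in error_sets[m])
        counts[who] += 1
    return counts


def error_report(
    predictions_by_method: Mapping[str, Sequence[ContextPrediction]],
    gold_docs: Sequence[AnnotatedDocument],
    category_assignments: Mapping[tuple[str, int], ErrorCategory] | None = None,
) -> tuple[list[ErrorRecord], pd.DataFrame]:
    """Collect every FP/FN into error records and tabulate frequencies.

    Error categories are supplied externally (by human annotation); the
    function validates that categories are only assigned to actual errors
    and computes, per (method, polarity, category), counts and percentages
    of the polarity total.
    """
    gold = _gold_map(gold_docs)
    errors: dict[tuple[str, int, str], set[str]] = {}
    for method, preds in predictions_by_method.items():
        for pred in preds:
            key = (pred.doc_id, pred.entity_index)
            if key not in gold:
                raise ValidationError(
                    f"prediction for entity {pred.entity_index} has no gold label",
                    doc_id=pred.doc_id,
                )
            gold_label, _cat = gold[key]
            if pred.label is gold_label:
                continue
            polarity = (
                "false_positive" if pred.label is NegationLabel.NEGATED else "false_negative"
            )
            errors.setdefault((pred.doc_id, pred.entity_index, polarity), set()).add(method)

    assigned = dict(category_assignments or {})
    error_keys = {(d, i) for d, i, _ in errors}
    for key in assigned:
        if key not in error_keys:
            raise ValidationError(
                f"error category assigned to non-error entity {key[1]}", doc_id=key[0]
            )

    records = [
        ErrorRecord(
            doc_id=d,
            entity_index=i,
            polarity=pol,
            methods=frozenset(methods),
            category=assigned.get((d, i)),
        )
        for (d, i, pol), methods in sorted(errors.items())
    ]

    rows = []
    for method in sorted(predictions_by_method):
        for polarity in ("false_positive", "false_negative"):
            rel = [r for r in records if method in r.methods and r.polarity == polarity]
            total = len(rel)
            by_cat = Counter(r.category for r in rel if r.category is not None)
            for cat in ErrorCategory:
                count = by_cat.get(cat, 0)
                rows.append(
                    {
                        "method": method,
                        "polarity": polarity,
                        "category": cat.value,
                        "count": count,
                        "percent": (100.0 * count / total) if total else 0.0,
                    }
                )
            rows.append(
                {
                    "method": method,
                    "polarity": polarity,
                    "category": "total",
                    "count": total,
                    "percent": 100.0 if total else 0.0,
                }
            )
    return records, pd.DataFrame(rows)
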