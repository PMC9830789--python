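import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from clinneg.corpus import (
    AnnotatedDocument,
    ContextPrediction,
    EntityAnnotation,
    NegationLabel,
    RecordCategory,
)
from clinneg.errors import ConfigurationError, ValidationError
from clinneg.evaluation import (
    CVConfig,
    ErrorCategory,
    MetricsReport,
    cohens_kappa,
    compute_metrics,
    ensemble_predictions,
    error_intersections,
    error_report,
    majority_vote,
    make_folds,
)
from oracles import oracle_majority

NEG, POS = NegationLabel.NOT_NEGATED, NegationLabel.NEGATED


class TestMakeFolds:
    def test_ten_items_ten_singleton_folds(self):
        folds = make_folds(10, CVConfig(k=10, grouping="entity"))
        assert sorted(np.bincount(folds)) == [1] * 10

    def test_paper_scale_fold_sizes(self):
        # 12419 items over 10 folds: integer division oracle
        folds = make_folds(12419, CVConfig(k=10, grouping="entity"))
        sizes = sorted(np.bincount(folds, minlength=10))
        assert sizes == [1241] + [1242] * 9

    def test_same_seed_identical(self):
        a = make_folds(100, CVConfig(k=5, seed=42, grouping="entity"))
        b = make_folds(100, CVConfig(k=5, seed=42, grouping="entity"))
        np.testing.assert_array_equal(a, b)

    def test_too_few_items_rejected(self):
        with pytest.raises(ConfigurationError):
            make_folds(3, CVConfig(k=10))

    def test_record_grouping_keeps_groups_together(self):
        groups = [f"r{i // 3}" for i in range(60)]
        folds = make_folds(60, CVConfig(k=5, seed=1, grouping="record"), groups=groups)
        for g in set(groups):
            member_folds = {folds[i] for i in range(60) if groups[i] == g}
            assert len(member_folds) == 1

    @given(n=st.integers(10, 300), k=st.integers(2, 10), seed=st.integers(0, 99))
    @settings(max_examples=60, deadline=None)
    def test_partition_property(self, n, k, seed):
        folds = make_folds(n, CVConfig(k=k, seed=seed, grouping="entity"))
        sizes = np.bincount(folds, minlength=k)
        assert sizes.sum() == n
        assert sizes.max() - sizes.min() <= 1


class TestMajorityVote:
    def _pred(self, label, method="m"):
        return ContextPrediction("d", 0, label, method=method)

    def test_two_to_one(self):
        p = majority_vote([self._pred(POS), self._pred(POS), self._pred(NEG)])
        assert p.label is POS
        assert p.method == "ensemble" and p.probability is None

    def test_unanimous_not_negated(self):
        p = majority_vote([self._pred(NEG)] * 3)
        assert p.label is NEG

    def test_all_eight_combinations_match_oracle(self):
        for combo in itertools.product([POS, NEG], repeat=3):
            want = oracle_majority(tuple(c.value for c in combo))
            got = majority_vote([self._pred(c) for c in combo])
            assert got.label.value == want

    def test_wrong_count_rejected(self):
        with pytest.raises(ValidationError):
            majority_vote([self._pred(POS), self._pred(NEG)])

    def test_mismatched_entities_rejected(self):
        preds = [
            ContextPrediction("d", 0, POS),
            ContextPrediction("d", 1, POS),
            ContextPrediction("d", 0, NEG),
        ]
        with pytest.raises(ValidationError):
            majority_vote(preds)

    def test_ensemble_requires_three_sets(self):
        sets = [[ContextPrediction("d", 0, POS)]] * 2
        with pytest.raises(ValidationError):
            ensemble_predictions(sets)


def _gold_doc(doc_id, labels, category=RecordCategory.RADIOLOGY_REPORT):
    # one entity per word "t0 t1 ..." with given gold labels
    text = " ".join(f"t{i}" for i in range(len(labels)))
    ents = []
    pos = 0
    for i, lab in enumerate(labels):
        w = f"t{i}"
        ents.append(EntityAnnotation(pos, pos + len(w), w, gold_label=lab))
        pos += len(w) + 1
    return AnnotatedDocument(doc_id, text, category, tuple(ents))


class TestComputeMetrics:
    def test_hand_computed_two_thirds(self):
        gold = _gold_doc("d", [POS, POS, POS, NEG, NEG])
        preds = [
            ContextPrediction("d", 0, POS),  # tp
            ContextPrediction("d", 1, POS),  # tp
            ContextPrediction("d", 2, NEG),  # fn
            ContextPrediction("d", 3, POS),  # fp
            ContextPrediction("d", 4, NEG),  # tn
        ]
        (rep,) = [r for r in compute_metrics(preds, [gold]) if r.stratum == "all"]
        assert rep.precision == pytest.approx(2 / 3)
        assert rep.recall == pytest.approx(2 / 3)
        assert rep.f1 == pytest.approx(2 / 3)

    def test_perfect_predictions(self):
        gold = _gold_doc("d", [POS, NEG])
        preds = [ContextPrediction("d", 0, POS), ContextPrediction("d", 1, NEG)]
        (rep,) = [r for r in compute_metrics(preds, [gold]) if r.stratum == "all"]
        assert (rep.precision, rep.recall, rep.f1) == (1.0, 1.0, 1.0)

    def test_zero_predicted_positives_precision_absent(self):
        gold = _gold_doc("d", [POS, NEG])
        preds = [ContextPrediction("d", 0, NEG), ContextPrediction("d", 1, NEG)]
        (rep,) = [r for r in compute_metrics(preds, [gold]) if r.stratum == "all"]
        assert rep.precision is None
        assert rep.recall == 0.0

    def test_prediction_without_gold_rejected(self):
        gold = _gold_doc("d", [POS])
        preds = [ContextPrediction("d", 0, POS), ContextPrediction("d", 7, POS)]
        with pytest.raises(ValidationError):
            compute_metrics(preds, [gold])

    def test_missing_coverage_rejected(self):
        gold = _gold_doc("d", [POS, NEG])
        with pytest.raises(ValidationError):
            compute_metrics([ContextPrediction("d", 0, POS)], [gold])

    def test_per_category_strata(self):
        g1 = _gold_doc("a", [POS], RecordCategory.RADIOLOGY_REPORT)
        g2 = _gold_doc("b", [NEG], RecordCategory.DISCHARGE_LETTER)
        preds = [ContextPrediction("a", 0, POS), ContextPrediction("b", 0, NEG)]
        strata = {r.stratum for r in compute_metrics(preds, [g1, g2])}
        assert strata == {"all", "radiology_report", "discharge_letter"}

    @given(
        tp=st.integers(0, 100), fp=st.integers(0, 100),
        fn=st.integers(0, 100), tn=st.integers(0, 100),
    )
    @settings(max_examples=300, deadline=None)
    def test_f1_between_precision_and_recall(self, tp, fp, fn, tn):
        rep = MetricsReport.from_counts("all", tp, fp, fn, tn)
        if rep.precision is not None and rep.recall is not None and rep.f1 is not None:
            lo, hi = sorted([rep.precision, rep.recall])
            assert lo - 1e-12 <= rep.f1 <= hi + 1e-12
            if rep.precision == rep.recall:
                assert rep.f1 == pytest.approx(rep.precision)


class TestErrorIntersections:
    def test_disjoint_sets(self):
        counts = error_intersections({"A": {1}, "B": {2}, "C": {3}})
        assert counts[frozenset({"A"})] == 1
        assert counts[frozenset({"A", "B"})] == 0
        assert counts[frozenset({"A", "B", "C"})] == 0

    def test_nested_sets(self):
        counts = error_intersections({"A": {1, 2, 3}, "B": {2, 3}, "C": {3}})
        assert counts[frozenset({"A"})] == 1
        assert counts[frozenset({"A", "B"})] == 1
        assert counts[frozenset({"A", "B", "C"})] == 1

    def test_identical_sets(self):
        counts = error_intersections({"A": {1, 2}, "B": {1, 2}, "C": {1, 2}})
        assert counts[frozenset({"A", "B", "C"})] == 2
        assert sum(counts.values()) == 2

    def test_conservation(self, rng):
        for _ in range(20):
            sets = {
                m: set(rng.integers(0, 50, size=rng.integers(0, 30)).tolist())
                for m in ("A", "B", "C")
            }
            counts = error_intersections(sets)
            assert sum(counts.values()) == len(set().union(*sets.values()))


class TestCohensKappa:
    def test_identical_vectors(self):
        r = cohens_kappa(["x", "y", "x"], ["x", "y", "x"])
        assert r.kappa == pytest.approx(1.0)

    def test_hand_computed_zero(self):
        r = cohens_kappa(list("xxyy"), list("xyxy"))
        assert r.p_observed == pytest.approx(0.5)
        assert r.p_expected == pytest.approx(0.5)
        assert r.kappa == pytest.approx(0.0)

    def test_hand_computed_half(self):
        r = cohens_kappa(list("xxyy"), list("xxyx"))
        assert r.p_observed == pytest.approx(0.75)
        assert r.p_expected == pytest.approx(0.5)
        assert r.kappa == pytest.approx(0.5)

    def test_degenerate_single_category(self):
        r = cohens_kappa(["x", "x"], ["x", "x"])
        assert r.kappa is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            cohens_kappa(["x"], ["x", "y"])

    def test_symmetry_and_sklearn_agreement(self, rng):
        cats = np.array(["a", "b", "c", "d"])
        for _ in range(20):
            a = cats[rng.integers(0, 4, size=30)].tolist()
            b = cats[rng.integers(0, 4, size=30)].tolist()
            r_ab = cohens_kappa(a, b)
            r_ba = cohens_kappa(b, a)
            assert r_ab.kappa == pytest.approx(r_ba.kappa)
            assert r_ab.kappa == pytest.approx(cohen_kappa_score(a, b))


class TestErrorReport:
    def test_zero_errors_empty_report(self):
        gold = _gold_doc("d", [POS, NEG])
        preds = {"rule": [ContextPrediction("d", 0, POS), ContextPrediction("d", 1, NEG)]}
        records, table = error_report(preds, [gold])
        assert records == []
        assert table[table["category"] == "total"]["count"].sum() == 0

    def test_percentages_75_25(self):
        gold = _gold_doc("d", [NEG, NEG, NEG, NEG])
        preds = {"m": [ContextPrediction("d", i, POS) for i in range(4)]}  # 4 FPs
        cats = {
            ("d", 0): ErrorCategory.SCOPE,
            ("d", 1): ErrorCategory.SCOPE,
            ("d", 2): ErrorCategory.SCOPE,
            ("d", 3): ErrorCategory.MINUS,
        }
        _, table = error_report(preds, [gold], cats)
        fp = table[(table["polarity"] == "false_positive") & (table["method"] == "m")]
        assert float(fp[fp["category"] == "scope"]["percent"].iloc[0]) == pytest.approx(75.0)
        assert float(fp[fp["category"] == "minus"]["percent"].iloc[0]) == pytest.approx(25.0)

    def test_category_on_non_error_rejected(self):
        gold = _gold_doc("d", [POS])
        preds = {"m": [ContextPrediction("d", 0, POS)]}
        with pytest.raises(ValidationError):
            error_report(preds, [gold], {("d", 0): ErrorCategory.OTHER})

    def test_ten_error_categories(self):
        assert len(ErrorCategory) == 10

    def test_minus_shorthand_becomes_false_negative(self):
        # corpus with minus-noise negations and a lexicon lacking "-"
        from clinneg.rules import TriggerLexicon, classify_entities_rule
        from clinneg.synthetic import GeneratorConfig, NoiseRates, generate_corpus

        cfg = GeneratorConfig(
            n_documents=60, seed=13, negation_prevalence=0.5,
            noise=NoiseRates(minus=1.0),
        )
        docs, traces = generate_corpus(cfg)
        minus_keys = {
            (t.doc_id, t.entity_index) for t in traces if t.mechanism == "minus"
        }
        assert minus_keys, "fixture must produce minus-shorthand negations"
        lexicon = TriggerLexicon.default()
        preds = {"rule": [p for d in docs for p in classify_entities_rule(d, lexicon)]}
        records, _ = error_report(preds, docs)
        fn_keys = {
            (r.doc_id, r.entity_index)
            for r in records
            if r.polarity == "false_negative"
        }
        assert minus_keys <= fn_keys
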