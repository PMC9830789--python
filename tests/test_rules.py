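import numpy as np
import pytest

from clinneg.corpus import (
    AnnotatedDocument,
    EntityAnnotation,
    NegationLabel,
    RecordCategory,
)
from clinneg.errors import ConfigurationError
from clinneg.rules import (
    SentenceSpan,
    TriggerCategory,
    TriggerEntry,
    TriggerLexicon,
    classify_entities_rule,
    compile_lexicon,
    compute_scope,
    find_trigger_matches,
    insert_whitespace,
    split_sentences,
    tokenize,
)
from oracles import OracleEntry, oracle_negated_entities

F = TriggerCategory.NEGATION_FORWARD
B = TriggerCategory.NEGATION_BACKWARD
P = TriggerCategory.PSEUDO
T = TriggerCategory.TERMINATION

CAT = RecordCategory.GENERAL_PRACTITIONER


def doc_of(text: str, *spans: tuple[int, int]) -> AnnotatedDocument:
    ents = tuple(EntityAnnotation(s, e, text[s:e]) for s, e in spans)
    return AnnotatedDocument("t", text, CAT, ents)


def labels(doc, lexicon, **kw):
    return [p.label for p in classify_entities_rule(doc, lexicon, **kw)]


class TestCompileLexicon:
    def test_two_entries(self):
        lx = compile_lexicon([TriggerEntry("geen", F), TriggerEntry("maar", T)])
        assert len(lx) == 2

    def test_duplicate_rejected_naming_pattern(self):
        with pytest.raises(ConfigurationError, match="geen"):
            compile_lexicon([TriggerEntry("geen", F), TriggerEntry("geen", F)])

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            compile_lexicon([])

    def test_bad_regex_names_pattern(self):
        with pytest.raises(ConfigurationError, match=r"\(unclosed"):
            compile_lexicon([TriggerEntry("(unclosed", F)])

    def test_packaged_default_preserves_entry_count(self, default_lexicon):
        # count oracle: data lines in the packaged TSV
        from importlib import resources

        raw = resources.files("clinneg").joinpath("lexicons/dutch_default.tsv").read_text("utf-8")
        expected = sum(
            1 for ln in raw.splitlines() if ln.strip() and not ln.lstrip().startswith("#")
        )
        assert len(default_lexicon) == expected == 40

    def test_max_scope_on_termination_rejected(self):
        with pytest.raises(ConfigurationError):
            TriggerEntry("maar", T, max_scope=3)


class TestSplitSentences:
    def test_period_splitting(self):
        assert len(split_sentences("Geen koorts. Wel hoesten.")) == 2

    def test_newline_is_boundary(self):
        sents = split_sentences("geen koorts\nwel hoesten")
        assert len(sents) == 2

    def test_empty_text(self):
        assert split_sentences("") == []

    def test_tokens_cover_non_whitespace(self):
        text = "Geen koorts, wel (lichte) pijn! En verder niets."
        for sent in split_sentences(text):
            covered = set()
            for s, e in sent.tokens:
                covered.update(range(s, e))
            expected = {
                i for i in range(sent.start, sent.end) if not text[i].isspace()
            }
            assert covered == expected

    def test_decimal_number_does_not_split(self):
        assert len(split_sentences("temp tot 38.2 gemeten.")) == 1

    def test_custom_splitter_injection(self):
        def one_big_sentence(text):
            toks = tokenize(text)
            return [SentenceSpan(toks[0][0], toks[-1][1], tuple(toks))]

        sents = split_sentences("a. b. c.", splitter=one_big_sentence)
        assert len(sents) == 1


class TestTokenize:
    def test_trailing_hyphen_stays_attached(self):
        spans = tokenize("bleek-, misselijk-, klam+")
        words = ["bleek-", ",", "misselijk-", ",", "klam", "+"]
        assert ["bleek-, misselijk-, klam+"[s:e] for s, e in spans] == words

    def test_inner_hyphen_splits(self):
        text = "infectie-gerelateerd"
        words = [text[s:e] for s, e in tokenize(text)]
        assert words == ["infectie", "-", "gerelateerd"]


class TestFindTriggerMatches:
    def test_pseudo_takes_precedence(self):
        lx = compile_lexicon([TriggerEntry("niet", F), TriggerEntry("niet alleen", P)])
        text = "niet alleen pijn"
        ms = find_trigger_matches(split_sentences(text)[0], text, lx)
        assert [(m.entry.category) for m in ms] == [P]

    def test_no_trigger_substring(self):
        lx = compile_lexicon([TriggerEntry("geen", F)])
        text = "alles rustig vandaag"
        assert find_trigger_matches(split_sentences(text)[0], text, lx) == []

    def test_longest_match_wins(self):
        lx = compile_lexicon(
            [TriggerEntry("no", F), TriggerEntry("no evidence of", F)]
        )
        text = "no evidence of velatose"
        ms = find_trigger_matches(split_sentences(text)[0], text, lx)
        assert [m.entry.pattern for m in ms] == ["no evidence of"]

    def test_case_insensitive(self):
        lx = compile_lexicon([TriggerEntry("geen", F)])
        text = "GEEN flebargie"
        ms = find_trigger_matches(split_sentences(text)[0], text, lx)
        assert len(ms) == 1

    def test_no_match_inside_word(self):
        lx = compile_lexicon([TriggerEntry("niet", F)])
        text = "genieten van rust"
        assert find_trigger_matches(split_sentences(text)[0], text, lx) == []


class TestComputeScope:
    def _match(self, text, lx):
        sent = split_sentences(text)[0]
        ms = find_trigger_matches(sent, text, lx)
        negs = [m for m in ms if m.entry.category in (F, B)]
        terms = [m for m in ms if m.entry.category is T]
        return sent, negs[0], terms

    def test_forward_default_scope_to_sentence_end(self):
        lx = compile_lexicon([TriggerEntry("no signs of", F)])
        sent, m, terms = self._match("no signs of acute velatose links boven", lx)
        scope = compute_scope(m, sent, terms)
        assert (scope.token_start, scope.token_end) == (3, 7)

    def test_forward_truncated_by_termination(self):
        lx = compile_lexicon([TriggerEntry("no signs of", F), TriggerEntry("but", T)])
        sent, m, terms = self._match("no signs of infection but pneumonia persists", lx)
        scope = compute_scope(m, sent, terms)
        assert (scope.token_start, scope.token_end) == (3, 4)

    def test_forward_trigger_at_final_token_empty_scope(self):
        lx = compile_lexicon([TriggerEntry("geen", F)])
        sent, m, terms = self._match("verder geen", lx)
        scope = compute_scope(m, sent, terms)
        assert scope.token_start == scope.token_end

    def test_max_scope_limits_word_count(self):
        lx = compile_lexicon([TriggerEntry("no", F, max_scope=2)])
        sent, m, terms = self._match("no a b c d e", lx)
        scope = compute_scope(m, sent, terms)
        assert (scope.token_start, scope.token_end) == (1, 3)

    def test_backward_scope(self):
        lx = compile_lexicon([TriggerEntry("uitgesloten", B)])
        text = "acute flebargie uitgesloten"
        sent, m, terms = self._match(text, lx)
        scope = compute_scope(m, sent, terms)
        assert (scope.direction, scope.token_start, scope.token_end) == ("backward", 0, 2)


class TestClassifyEntities:
    def test_termination_saves_second_entity(self, english_lexicon):
        text = "No signs of infection, but pneumonia persists"
        doc = doc_of(text, (12, 21), (27, 36))
        assert labels(doc, english_lexicon) == [
            NegationLabel.NEGATED,
            NegationLabel.NOT_NEGATED,
        ]

    def test_no_triggers_all_not_negated(self, default_lexicon):
        doc = doc_of("alles rustig met de flebargie vandaag", (20, 29))
        assert labels(doc, default_lexicon) == [NegationLabel.NOT_NEGATED]

    def test_default_scope_false_positive_documented(self):
        # list-style sentence: default sentence scope over-reaches
        lx = compile_lexicon([TriggerEntry("geen", F)])
        text = "geen buikpijn, schaafwond aan been"
        doc = doc_of(text, (5, 13), (15, 34))
        assert labels(doc, lx) == [NegationLabel.NEGATED, NegationLabel.NEGATED]

    def test_entity_overlapping_trigger_not_self_negated(self):
        lx = compile_lexicon([TriggerEntry("geen eetlust", F)])
        text = "geen eetlust vandaag"
        doc = doc_of(text, (5, 12))  # "eetlust" inside the trigger span
        assert labels(doc, lx) == [NegationLabel.NOT_NEGATED]

    def test_negation_does_not_cross_sentences(self):
        lx = compile_lexicon([TriggerEntry("geen", F)])
        text = "geen koorts. flebargie aanwezig."
        doc = doc_of(text, (13, 22))
        assert labels(doc, lx) == [NegationLabel.NOT_NEGATED]

    def test_method_and_probability(self, default_lexicon, tiny_corpus):
        preds = classify_entities_rule(tiny_corpus[0], default_lexicon)
        assert all(p.method == "rule" and p.probability is None for p in preds)

    def test_determinism(self, default_lexicon, tiny_corpus):
        a = classify_entities_rule(tiny_corpus[0], default_lexicon)
        b = classify_entities_rule(tiny_corpus[0], default_lexicon)
        assert a == b

    def test_preprocess_restores_sentence_boundary(self):
        # a period glued to a parenthesis defeats naive splitting, so the
        # forward scope leaks into the next statement; whitespace insertion
        # restores the boundary
        lx = compile_lexicon([TriggerEntry("geen", F)])
        text = "geen koorts.(flebargie aanwezig)"
        doc = doc_of(text, (13, 22))  # "flebargie"
        assert labels(doc, lx, preprocess=False) == [NegationLabel.NEGATED]
        assert labels(doc, lx, preprocess=True) == [NegationLabel.NOT_NEGATED]


class TestInsertWhitespace:
    def test_parentheses_separated(self):
        new, _pos = insert_whitespace("a(geen b)")
        assert "( geen" in new and "a (" in new

    def test_offsets_map_monotone(self):
        text = "x(y)z"
        new, pos = insert_whitespace(text)
        assert pos == sorted(pos)
        for i, ch in enumerate(text):
            assert new[pos[i]] == ch


# ---------------------------------------------------------------------------
# properties against the brute-force oracle


VOCAB = ["druk", "pijn", "licht", "matig", "controle", "status", "rustig", "dag"]
TERMS = ["flebargie", "velatose", "cardunitis"]
TRIGGERS_F = ["geen", "niet", "geen tekenen van"]
TRIGGERS_B = ["uitgesloten", "niet aangetoond"]
TERMINATIONS = ["maar", "echter"]


def _random_sentence(rng, with_entities=True, max_tokens=12):
    n = int(rng.integers(3, max_tokens + 1))
    tokens = []
    while len(tokens) < n:
        r = rng.random()
        if r < 0.18:
            tokens.extend(TRIGGERS_F[int(rng.integers(0, len(TRIGGERS_F)))].split())
        elif r < 0.26:
            tokens.extend(TRIGGERS_B[int(rng.integers(0, len(TRIGGERS_B)))].split())
        elif r < 0.34:
            tokens.append(TERMINATIONS[int(rng.integers(0, len(TERMINATIONS)))])
        elif r < 0.60:
            tokens.append(TERMS[int(rng.integers(0, len(TERMS)))])
        else:
            tokens.append(VOCAB[int(rng.integers(0, len(VOCAB)))])
    tokens = tokens[:max_tokens]
    entity_ranges = [
        (i, i + 1) for i, t in enumerate(tokens) if t in TERMS
    ]
    return tokens, entity_ranges


def _engine_labels(tokens, entity_ranges, entries):
    text = " ".join(tokens)
    starts = []
    pos = 0
    for t in tokens:
        starts.append(pos)
        pos += len(t) + 1
    spans = [(starts[lo], starts[hi - 1] + len(tokens[hi - 1])) for lo, hi in entity_ranges]
    doc = doc_of(text, *spans)
    lx = compile_lexicon(entries)
    return [l is NegationLabel.NEGATED for l in labels(doc, lx)]


def _base_entries():
    return (
        [TriggerEntry(p, F) for p in TRIGGERS_F]
        + [TriggerEntry(p, B) for p in TRIGGERS_B]
        + [TriggerEntry(p, T) for p in TERMINATIONS]
    )


def _oracle_entries(entries):
    return [
        OracleEntry(tuple(e.pattern.lower().split()), e.category.value, e.max_scope)
        for e in entries
    ]


class TestOracleEquivalence:
    def test_engine_matches_brute_force_on_short_sentences(self, rng):
        entries = _base_entries()
        oracle_entries = _oracle_entries(entries)
        checked = 0
        for _ in range(200):
            tokens, ents = _random_sentence(rng)
            if not ents:
                continue
            got = _engine_labels(tokens, ents, entries)
            want = oracle_negated_entities(tokens, oracle_entries, ents)
            assert got == want, f"disagreement on {tokens!r}"
            checked += 1
        assert checked > 100

    def test_pseudo_precedence_never_adds_negations(self, rng):
        base = _base_entries()
        extended = base + [TriggerEntry("geen tekenen", P), TriggerEntry("niet pijn", P)]
        for _ in range(150):
            tokens, ents = _random_sentence(rng)
            if not ents:
                continue
            before = _engine_labels(tokens, ents, base)
            after = _engine_labels(tokens, ents, extended)
            assert all(b or not a for a, b in zip(after, before))

    def test_termination_monotonicity(self, rng):
        base = _base_entries()
        extended = base + [TriggerEntry("controle", T), TriggerEntry("status", T)]
        for _ in range(150):
            tokens, ents = _random_sentence(rng)
            if not ents:
                continue
            before = _engine_labels(tokens, ents, base)
            after = _engine_labels(tokens, ents, extended)
            assert all(b or not a for a, b in zip(after, before))
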