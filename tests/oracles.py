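"""Independent brute-force oracles used to freeze expected values.

These deliberately re-implement the documented semantics in the most
literal way possible (token-level enumeration, no shared code with the
package), so they can arbitrate the real implementations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass


@dataclass(frozen=True)
class OracleEntry:
    words: tuple[str, ...]  # lower-cased literal phrase, split into words
    category: str  # negation_forward | negation_backward | pseudo | termination
    max_scope: int | None = None


def oracle_find_matches(tokens: list[str], entries: list[OracleEntry]):
    """Every literal phrase occurrence, then pseudo precedence and
    longest-match resolution, enumerated naively.

    A match is (entry, start, end) over token indices. 'Longest' is measured
    in characters of the matched phrase, mirroring the char-level engine;
    ties break on start, then category, then phrase.
    """
    low = [t.lower() for t in tokens]
    candidates = []
    for entry in entries:
        k = len(entry.words)
        for i in range(len(low) - k + 1):
            if tuple(low[i : i + k]) == entry.words:
                candidates.append((entry, i, i + k))

    pseudo_spans = [(s, e) for (entry, s, e) in candidates if entry.category == "pseudo"]
    candidates = [
        (entry, s, e)
        for (entry, s, e) in candidates
        if not (
            entry.category in ("negation_forward", "negation_backward")
            and any(ps <= s and e <= pe for ps, pe in pseudo_spans)
        )
    ]

    def char_len(entry: OracleEntry) -> int:
        return len(" ".join(entry.words))

    order = sorted(
        candidates,
        key=lambda c: (-char_len(c[0]), c[1], c[0].category, " ".join(c[0].words)),
    )
    kept = []
    for cand in order:
        _, s, e = cand
        if all(e <= ks or s >= ke for _, ks, ke in kept):
            kept.append(cand)
    return kept


def oracle_negated_entities(
    tokens: list[str], entries: list[OracleEntry], entity_ranges: list[tuple[int, int]]
) -> list[bool]:
    """Apply the scope definition literally over one sentence.

    Forward scope: tokens after the trigger up to sentence end; backward:
    before the trigger from sentence start; truncated at the nearest
    termination match in the scope direction and at max_scope words. An
    entity is negated iff one of its tokens lies in at least one scope and
    it does not overlap the trigger's own tokens.
    """
    matches = oracle_find_matches(tokens, entries)
    terminations = [(s, e) for entry, s, e in matches if entry.category == "termination"]
    scopes = []  # (trigger token set, scope token set)
    for entry, s, e in matches:
        if entry.category == "negation_forward":
            lo, hi = e, len(tokens)
            for ts, _te in terminations:
                if ts >= lo:
                    hi = min(hi, ts)
            if entry.max_scope is not None:
                hi = min(hi, lo + entry.max_scope)
            scopes.append((set(range(s, e)), set(range(lo, max(lo, hi)))))
        elif entry.category == "negation_backward":
            lo, hi = 0, s
            for _ts, te in terminations:
                if te <= hi:
                    lo = max(lo, te)
            if entry.max_scope is not None:
                lo = max(lo, hi - entry.max_scope)
            scopes.append((set(range(s, e)), set(range(min(lo, hi), hi))))
    out = []
    for lo, hi in entity_ranges:
        ent = set(range(lo, hi))
        negated = any((not ent & trig) and (ent & scope) for trig, scope in scopes)
        out.append(negated)
    return out


def oracle_first_bpe_merge(texts: list[str]) -> tuple[str, str]:
    """Most frequent adjacent character pair (lexicographic tie-break)."""
    counts: Counter = Counter()
    for text in texts:
        for word in text.split():
            for a, b in zip(word, word[1:]):
                counts[(a, b)] += 1
    best = max(counts.values())
    return min(p for p, c in counts.items() if c == best)


def oracle_majority(labels: tuple[str, str, str]) -> str:
    """Exhaustive majority by counting."""
    counts = Counter(labels)
    return counts.most_common(1)[0][0]
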