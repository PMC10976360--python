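"""Translation-quality metrics and the four-way error taxonomy.

Predicted encoded queries are scored against gold references with
(1) exact-match accuracy — a pair scores 1 iff the whitespace-token
sequences are identical — and (2) a corpus-level 4-gram BLEU score with
brevity penalty on a 0–100 scale, computed on the encoded strings exactly
as the model emits them (queries are code-like; a linguistic tokenizer
would distort the n-grams).

Incorrect predictions are additionally classified by the aspect of the
logical form they get wrong: ``syntax`` (the decoded query fails SPARQL
parsing), ``query_structure`` (the predicate-abstracted triple-pattern
multiset or SELECT arity differs), ``relation`` (structures align but at
least one predicate differs), and ``function`` (the comparative FILTER
structure differs).  Non-syntax categories may co-occur; the report's
percentages are over all examples.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from . import codec
from .kg import DEFAULT_PROLOGUE, OntologySchema, SparqlSyntaxError, parse_select
from .pipeline import ExpandError, _parse_query

__all__ = [
    "ERROR_CATEGORIES",
    "EvalPair",
    "EvalReport",
    "DatasetError",
    "exact_match_accuracy",
    "corpus_bleu",
    "classify_errors",
    "evaluate",
]

ERROR_CATEGORIES = ("syntax", "query_structure", "relation", "function")


class DatasetError(ValueError):
    """A *gold* query is broken — a dataset fault, not a model error."""


@dataclass(frozen=True)
class EvalPair:
    gold: str
    predicted: str
    question: str = ""


@dataclass(frozen=True)
class EvalReport:
    accuracy_pct: float
    corpus_score: float
    error_breakdown: dict = field(default_factory=dict)
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "accuracy_pct": self.accuracy_pct,
            "corpus_score": self.corpus_score,
            "error_breakdown": dict(self.error_breakdown),
            "n": self.n,
        }


def _tokens(text: str) -> list[str]:
    return text.split()


def exact_match_accuracy(pairs: Sequence[EvalPair]) -> float:
    """Percentage of pairs whose token sequences match exactly
    (whitespace runs collapsed, case-sensitive)."""
    if not pairs:
        raise ValueError("empty pair list")
    hits = sum(_tokens(p.predicted) == _tokens(p.gold) for p in pairs)
    return 100.0 * hits / len(pairs)


def corpus_bleu(pairs: Sequence[EvalPair], max_n: int = 4) -> float:
    """Corpus-level BLEU with brevity penalty, 0–100 scale.

    Whitespace tokenization; exponential smoothing for zero higher-order
    n-gram counts.  By the mteval convention a corpus with zero unigram
    matches scores exactly 0.
    """
    if not pairs:
        raise ValueError("empty pair list")
    correct = [0] * max_n
    total = [0] * max_n
    cand_len = 0
    ref_len = 0
    for p in pairs:
        cand = _tokens(p.predicted)
        ref = _tokens(p.gold)
        cand_len += len(cand)
        ref_len += len(ref)
        for n in range(1, max_n + 1):
            cgrams = Counter(
                tuple(cand[i : i + n]) for i in range(len(cand) - n + 1)
            )
            rgrams = Counter(
                tuple(ref[i : i + n]) for i in range(len(ref) - n + 1)
            )
            correct[n - 1] += sum(
                min(c, rgrams[g]) for g, c in cgrams.items()
            )
            total[n - 1] += max(len(cand) - n + 1, 0)
    if cand_len == 0 or total[0] == 0 or correct[0] == 0:
        return 0.0
    smooth = 1.0
    log_sum = 0.0
    for n in range(max_n):
        if total[n] == 0:
            # candidates shorter than n tokens across the corpus
            precision = 100.0
        elif correct[n] == 0:
            smooth *= 2.0
            precision = 100.0 / (smooth * total[n])
        else:
            precision = 100.0 * correct[n] / total[n]
        log_sum += math.log(precision)
    bp = 1.0 if cand_len >= ref_len else math.exp(1.0 - ref_len / cand_len)
    return bp * math.exp(log_sum / max_n)


# ---------------------------------------------------------------------------
# Error taxonomy


def _structure(sparql: str):
    """(abstract-pattern multiset, arity, predicate multiset, filter
    multiset) of a decoded query; triple patterns inside OPTIONAL blocks
    are flattened with a marker."""
    select_vars, items = _parse_query(sparql)

    def kind(term: str) -> str:
        if term.startswith("?"):
            return "var"
        if term.startswith(('"', "'")):
            return "literal"
        return "iri"

    patterns: Counter = Counter()
    predicates: Counter = Counter()
    filters: Counter = Counter()

    def visit(items, optional: bool):
        for it in items:
            if it.kind == "triple":
                s, p, o = it.terms
                patterns[(kind(s), kind(o), optional)] += 1
                predicates[p] += 1
            elif it.kind == "values":
                patterns[("values", "", optional)] += 1
            elif it.kind == "filter":
                ops = tuple(re.findall(r"&&|\|\||<|>|>=|<=|!=|=", it.raw))
                filters[ops] += 1
            elif it.kind == "optional":
                inner = it.raw.strip()
                inner = inner[inner.index("{") + 1 : inner.rindex("}")]
                _, sub = _parse_query(f"SELECT ?x WHERE {{{inner}}}")
                visit(sub, True)

    visit(items, False)
    return patterns, len(select_vars), predicates, filters


def classify_errors(pair: EvalPair, schema: OntologySchema) -> set[str]:
    """Assign error categories to one prediction (empty set iff exact)."""
    try:
        gold_sparql = codec.decode(pair.gold)
        parse_select(DEFAULT_PROLOGUE + "\n" + gold_sparql)
        gold_sig = _structure(gold_sparql)
    except (codec.DecodeError, SparqlSyntaxError, ExpandError) as exc:
        raise DatasetError(f"gold query is invalid: {exc}")

    if _tokens(pair.predicted) == _tokens(pair.gold):
        return set()

    try:
        pred_sparql = codec.decode(pair.predicted)
        parse_select(DEFAULT_PROLOGUE + "\n" + pred_sparql)
    except (codec.DecodeError, SparqlSyntaxError):
        return {"syntax"}
    try:
        pred_sig = _structure(pred_sparql)
    except ExpandError:
        return {"query_structure"}

    g_patterns, g_arity, g_preds, g_filters = gold_sig
    p_patterns, p_arity, p_preds, p_filters = pred_sig
    out: set[str] = set()
    if g_patterns != p_patterns or g_arity != p_arity:
        out.add("query_structure")
    elif g_preds != p_preds:
        out.add("relation")
    if g_filters != p_filters:
        out.add("function")
    return out


def evaluate(pairs: Sequence[EvalPair], schema: OntologySchema) -> EvalReport:
    """Aggregate accuracy, corpus score and the error-category breakdown
    (percentages over all ``n`` examples; categories may co-occur)."""
    if not pairs:
        raise ValueError("empty pair list")
    counts = {c: 0 for c in ERROR_CATEGORIES}
    for p in pairs:
        for cat in classify_errors(p, schema):
            counts[cat] += 1
    n = len(pairs)
    return EvalReport(
        accuracy_pct=exact_match_accuracy(pairs),
        corpus_score=corpus_bleu(pairs),
        error_breakdown={c: 100.0 * v / n for c, v in counts.items()},
        n=n,
    )
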