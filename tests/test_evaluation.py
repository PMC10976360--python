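import math
import random

import pytest

from chemkgqa.evaluation import (
    DatasetError,
    EvalPair,
    classify_errors,
    corpus_bleu,
    evaluate,
    exact_match_accuracy,
)
from chemkgqa.fixtures import (
    CORRUPTION_MODES,
    INTENDED_CATEGORY,
    CorruptionError,
    CorruptionSpec,
    corrupt,
)

GOLD = (
    "SELECT var_SpeciesIRI var_ChargeValue WHERE &lcub; "
    "var_SpeciesIRI os:hasCharge var_ChargeIRI . "
    "var_ChargeIRI os:value var_ChargeValue . &rcub;"
)


class TestExactMatch:
    def test_identity_scores_hundred(self):
        pairs = [EvalPair(GOLD, GOLD), EvalPair(GOLD, GOLD)]
        assert exact_match_accuracy(pairs) == 100.0

    def test_half_matching(self):
        pairs = [EvalPair(GOLD, GOLD), EvalPair(GOLD, GOLD + " extra")]
        assert exact_match_accuracy(pairs) == 50.0

    def test_single_token_difference_scores_zero(self):
        pred = GOLD.replace("os:hasCharge", "os:hasMolecularWeight")
        assert exact_match_accuracy([EvalPair(GOLD, pred)]) == 0.0

    def test_whitespace_runs_collapse(self):
        assert exact_match_accuracy([EvalPair("a  b\nc", "a b c")]) == 100.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            exact_match_accuracy([])


class TestCorpusBleu:
    def test_identity_corpus_scores_hundred(self, gold_dataset):
        examples, _ = gold_dataset
        pairs = [EvalPair(ex.encoded_query, ex.encoded_query) for ex in examples]
        assert corpus_bleu(pairs) == pytest.approx(100.0)
        assert exact_match_accuracy(pairs) == 100.0

    def test_disjoint_tokens_score_zero(self):
        pairs = [EvalPair("a b c d e", "v w x y z")]
        assert corpus_bleu(pairs) == 0.0

    def test_two_sentence_toy_corpus_matches_reference_arithmetic(self):
        """Independent oracle: explicit n-gram counts and the BLEU formula.

        cand1 "a b c d e f" vs ref1 "a b c d e f g": 6/6, 5/5, 4/4, 3/3.
        cand2 "x y z z w" vs ref2 "x y z w": 4/5, 3/4, 1/3, 0/2.
        Lengths 11 vs 11 -> brevity penalty 1.
        """
        pairs = [
            EvalPair("a b c d e f g", "a b c d e f"),
            EvalPair("x y z w", "x y z z w"),
        ]
        precisions = [(6 + 4) / (6 + 5), (5 + 3) / (5 + 4), (4 + 1) / (4 + 3), (3 + 0) / (3 + 2)]
        expected = 100.0 * math.exp(sum(math.log(p) for p in precisions) / 4)
        assert corpus_bleu(pairs) == pytest.approx(expected, abs=1e-4)
        assert expected == pytest.approx(76.71309447, abs=1e-4)

    def test_permutation_invariant(self, gold_dataset):
        examples, _ = gold_dataset
        pairs = [
            EvalPair(ex.encoded_query, ex.encoded_query + " x") for ex in examples
        ]
        shuffled = list(pairs)
        random.Random(5).shuffle(shuffled)
        assert corpus_bleu(pairs) == pytest.approx(corpus_bleu(shuffled))


class TestClassifyErrors:
    def test_exact_match_has_no_category(self, schema):
        assert classify_errors(EvalPair(GOLD, GOLD), schema) == set()

    def test_unbalanced_brace_is_syntax(self, schema):
        pred = GOLD.replace(" &rcub;", "")
        assert classify_errors(EvalPair(GOLD, pred), schema) == {"syntax"}

    def test_wrong_predicate_is_relation(self, schema):
        pred = GOLD.replace("os:hasCharge", "os:hasMolecularWeight")
        assert classify_errors(EvalPair(GOLD, pred), schema) == {"relation"}

    def test_inside_predicted_as_outside_is_function(self, schema):
        gold = (
            "SELECT var_SpeciesIRI WHERE &lcub; "
            "var_SpeciesIRI os:hasCharge var_ChargeIRI . "
            "var_ChargeIRI os:value var_v . "
            "FILTER (0 &lt; var_v && var_v &lt; 2) &rcub;"
        )
        pred = gold.replace(
            "FILTER (0 &lt; var_v && var_v &lt; 2)",
            "FILTER (var_v &lt; 0 || var_v &gt; 2)",
        )
        assert classify_errors(EvalPair(gold, pred), schema) == {"function"}

    def test_dropped_pattern_is_query_structure(self, schema):
        pred = GOLD.replace("var_ChargeIRI os:value var_ChargeValue . ", "")
        assert classify_errors(EvalPair(GOLD, pred), schema) == {"query_structure"}

    def test_broken_gold_is_a_dataset_fault(self, schema):
        with pytest.raises(DatasetError):
            classify_errors(EvalPair("SELECT var_x WHERE &lcub", GOLD), schema)

    def test_empty_set_iff_exact_match(self, schema, gold_dataset):
        examples, _ = gold_dataset
        rng = random.Random(13)
        for ex in examples[:15]:
            mode = rng.choice(CORRUPTION_MODES)
            try:
                pred = corrupt(ex, CorruptionSpec(mode, seed=rng.randrange(999)), schema)
            except CorruptionError:
                pred = ex.encoded_query
            pair = EvalPair(ex.encoded_query, pred, ex.question)
            cats = classify_errors(pair, schema)
            exact = exact_match_accuracy([pair]) == 100.0
            if exact:
                assert cats == set()
            else:
                # non-exact literal typos legitimately carry no category:
                # they are copy-correction territory, not taxonomy classes
                if mode != "typo_in_literal":
                    assert cats


class TestEvaluate:
    def test_gold_corpus_report(self, schema, gold_dataset):
        examples, _ = gold_dataset
        pairs = [
            EvalPair(ex.encoded_query, ex.encoded_query, ex.question)
            for ex in examples
        ]
        report = evaluate(pairs, schema)
        assert report.accuracy_pct == 100.0
        assert report.corpus_score == pytest.approx(100.0)
        assert all(v == 0.0 for v in report.error_breakdown.values())
        assert report.n == len(examples)

    def test_one_corrupted_of_ten(self, schema, gold_dataset):
        examples, _ = gold_dataset
        pairs = [
            EvalPair(ex.encoded_query, ex.encoded_query, ex.question)
            for ex in examples[:10]
        ]
        broken = corrupt(examples[0], CorruptionSpec("brace_break"), schema)
        pairs[0] = EvalPair(examples[0].encoded_query, broken, examples[0].question)
        report = evaluate(pairs, schema)
        assert report.accuracy_pct == pytest.approx(90.0)
        assert report.error_breakdown["syntax"] == pytest.approx(10.0)
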