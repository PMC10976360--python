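import random
import re

import pytest
import rdflib

from chemkgqa.codec import decode
from chemkgqa.generator import (
    OPERATORS,
    CanonicalQuery,
    ComparativeFilter,
    GeneratorConfig,
    QueryIntent,
    QuerySlots,
    VerbalizationForm,
    assemble_dataset,
    build_filter,
    build_species_grounding,
    collect_paraphrases,
    dataset_statistics,
    ground_query,
    sample_subgraph,
    verbalize,
)
from chemkgqa.generator import QAExample
from chemkgqa.kg import DEFAULT_PROLOGUE, OS, execute_select, parse_select


class TestComparativeFilter:
    @pytest.mark.parametrize(
        "f,expected",
        [
            (
                ComparativeFilter("higher", "BoilingPointValue", 373),
                "FILTER (?BoilingPointValue > 373)",
            ),
            (
                ComparativeFilter("lower", "x", 10.5),
                "FILTER (?x < 10.5)",
            ),
            (
                ComparativeFilter("inside", "x", 373, 350),
                "FILTER (350 < ?x && ?x < 373)",
            ),
            (
                ComparativeFilter("outside", "x", 373, 350),
                "FILTER (?x < 350 || ?x > 373)",
            ),
        ],
    )
    def test_realization(self, f, expected):
        assert build_filter(f) == expected

    def test_around_bounds_are_ninety_and_hundred_ten_percent(self):
        f = ComparativeFilter("around", "x", 100)
        assert f.bounds() == pytest.approx((90.0, 110.0))
        assert build_filter(f) == "FILTER (90 < ?x && ?x < 110)"

    def test_unordered_bounds_normalized(self):
        # users may supply "between 373 and 350"; lower bound is the min
        f = ComparativeFilter("inside", "x", 373, 350)
        assert f.bounds() == (350, 373)

    def test_around_requires_positive_threshold(self):
        with pytest.raises(ValueError):
            ComparativeFilter("around", "x", -5)

    def test_two_sided_operators_require_both_bounds(self):
        with pytest.raises(ValueError):
            ComparativeFilter("inside", "x", 1.0)

    def test_matches_agrees_with_realized_filter_semantics(self):
        f = ComparativeFilter("outside", "x", 10, 20)
        assert f.matches(9) and f.matches(21)
        assert not f.matches(15) and not f.matches(10)


class TestSampleSubgraph:
    def test_requested_out_degree(self, schema, rng):
        sub = sample_subgraph(schema, 2, rng)
        assert sub.out_degree == 2
        assert len({rel.iri for rel, _ in sub.edges}) == 2

    @pytest.mark.parametrize("bad", [0, 4])
    def test_out_degree_bounds_enforced(self, schema, rng, bad):
        with pytest.raises(ValueError):
            sample_subgraph(schema, bad, rng)

    def test_deterministic_for_fixed_seed(self, schema):
        a = sample_subgraph(schema, 3, random.Random(5))
        b = sample_subgraph(schema, 3, random.Random(5))
        assert a == b

    def test_identifier_relations_excluded_by_default(self, schema, rng):
        for _ in range(30):
            sub = sample_subgraph(schema, 3, rng)
            for rel, _ in sub.edges:
                assert not schema.is_identifier_relation(rel)


class TestSpeciesGrounding:
    def test_values_block_shape(self):
        block = build_species_grounding("benzene")
        assert 'VALUES (?species) { ("benzene") }' in block
        assert "?SpeciesIRI ?hasIdentifier ?IdentifierIRI ." in block
        assert "?IdentifierIRI os:value ?species ." in block

    def test_embedded_quote_escaped(self):
        block = build_species_grounding('2"-methyl')
        assert '("2\\"-methyl")' in block

    def test_empty_surface_rejected(self):
        with pytest.raises(ValueError):
            build_species_grounding("")


class TestGroundQuery:
    def test_property_lookup_shape(self, schema, store, rng):
        sub = sample_subgraph(schema, 1, rng)
        q = ground_query(sub, QueryIntent.PROPERTY_LOOKUP, store, rng, schema)
        assert q.intent is QueryIntent.PROPERTY_LOOKUP
        assert q.n_relations == 1
        assert q.groundings[0][0] == "species"
        assert "VALUES (?species)" in q.sparql
        q.validate(DEFAULT_PROLOGUE)
        assert execute_select(store, q.sparql)  # grounded => answerable

    def test_class_property_is_two_hop(self, schema, store, rng):
        for _ in range(50):
            sub = sample_subgraph(schema, 2, rng)
            kinds = {rel.local_name for rel, _ in sub.edges}
            if "hasChemicalClass" in kinds and len(kinds) == 2:
                break
        q = ground_query(sub, QueryIntent.CLASS_PROPERTY, store, rng, schema)
        assert "os:hasChemicalClass" in q.sparql
        assert q.sparql.count("?SpeciesIRI os:") == 2  # class hop + property hop
        assert execute_select(store, q.sparql)

    def test_incompatible_intent_rejected(self, schema, store, rng):
        sub = sample_subgraph(schema, 1, rng)  # single edge, no class guarantee
        from chemkgqa.generator import GenerationError

        with pytest.raises(GenerationError):
            ground_query(sub, QueryIntent.CLASS_PROPERTY, store, rng, schema)

    def test_species_search_matches_brute_force_scan(self, schema, store, fixture_kg):
        """Oracle equivalence: executing a species search returns exactly
        the species a direct scan of the instance triples admits."""
        g = rdflib.Graph()
        g.parse(data=fixture_kg.instances, format="nt")
        rng = random.Random(42)
        checked = 0
        for _ in range(25):
            sub = sample_subgraph(schema, rng.randint(1, 3), rng)
            q = ground_query(sub, QueryIntent.SPECIES_SEARCH, store, rng, schema)
            got = {row["SpeciesIRI"] for row in execute_select(store, q.sparql)}

            # independent scan: re-apply each criterion over raw triples
            rel_by_iri = {r.iri: r for r in schema.relations}
            survivors = set(str(s) for s in g.subjects(rdflib.RDF.type, OS.Species))
            filters = {f.variable: f for f in q.filters}
            grounded = dict(q.groundings)
            for rel_iri in q.relations:
                rel = rel_by_iri[rel_iri]
                base = rel.local_name.removeprefix("has")
                keep = set()
                for sp in survivors:
                    values = [
                        v
                        for o in g.objects(rdflib.URIRef(sp), rdflib.URIRef(rel_iri))
                        for v in g.objects(o, OS.value)
                    ]
                    if f"{base}Value" in filters:
                        f = filters[f"{base}Value"]
                        ok = any(_oracle_match(f, float(v)) for v in values)
                    else:
                        ok = grounded[rel.label] in {str(v) for v in values}
                    if ok:
                        keep.add(sp)
                survivors &= keep
            assert got == survivors
            assert q.groundings == () or got  # grounded queries answerable
            checked += 1
        assert checked == 25


def _oracle_match(f, x):
    # independent re-statement of the five operators' logical forms
    if f.op == "higher":
        return x > f.a
    if f.op == "lower":
        return x < f.a
    if f.op == "around":
        return 0.9 * f.a < x < 1.1 * f.a
    lo, hi = min(f.a, f.b), max(f.a, f.b)
    if f.op == "inside":
        return lo < x < hi
    return x < lo or x > hi


def _charge_lookup_query():
    return CanonicalQuery(
        sparql=(
            "SELECT ?ChargeValue\nWHERE {\n"
            + build_species_grounding("benzene")
            + "\n?SpeciesIRI os:hasCharge ?ChargeIRI .\n"
            "?ChargeIRI os:value ?ChargeValue .\n}"
        ),
        intent=QueryIntent.PROPERTY_LOOKUP,
        relations=(str(OS.hasCharge),),
        filters=(),
        groundings=(("species", "benzene"),),
        slots=QuerySlots(question_labels=("charge",), species_surface="benzene"),
    )


class TestVerbalize:
    @pytest.mark.parametrize(
        "form,expected",
        [
            (VerbalizationForm.INTERROGATIVE, "what is the charge of benzene?"),
            (VerbalizationForm.IMPERATIVE, "tell me about the charge of benzene."),
            (VerbalizationForm.KEYWORD, "charge of benzene"),
        ],
    )
    def test_three_forms_of_charge_lookup(self, form, expected):
        assert verbalize(_charge_lookup_query(), form) == expected

    def test_around_filter_verbalized_with_threshold(self, schema, store):
        rng = random.Random(0)
        for _ in range(200):
            sub = sample_subgraph(schema, 1, rng)
            q = ground_query(
                sub, QueryIntent.SPECIES_SEARCH, store, rng, schema,
                operators=("around",),
            )
            if q.filters:
                text = verbalize(q, VerbalizationForm.INTERROGATIVE)
                from chemkgqa.generator import format_number

                assert f"around {format_number(q.filters[0].a)}" in text
                return
        pytest.fail("no numeric species search generated")


class _EntityBreakingProvider:
    def paraphrase(self, question, n):
        return [
            question.replace("benzene", "C6H6"),
            "at what temperature does water boil?",
        ]


class _ExplodingProvider:
    def paraphrase(self, question, n):
        raise RuntimeError("remote API down")


class TestParaphrasing:
    def test_entity_preservation_filter(self):
        accepted = collect_paraphrases(
            "what is the boiling point of water?",
            ["water"],
            _EntityBreakingProvider(),
            n=5,
        )
        assert accepted == ["at what temperature does water boil?"]

    def test_entity_replacement_rejected(self):
        accepted = collect_paraphrases(
            "what is the charge of benzene?",
            ["benzene"],
            _EntityBreakingProvider(),
            n=5,
        )
        assert all("benzene" in p for p in accepted)
        assert not any("C6H6" in p for p in accepted)

    def test_keyword_form_never_paraphrased(self):
        class MustNotBeCalled:
            def paraphrase(self, question, n):  # pragma: no cover
                raise AssertionError("provider called on keyword form")

        assert (
            collect_paraphrases(
                "charge of benzene",
                ["benzene"],
                MustNotBeCalled(),
                form=VerbalizationForm.KEYWORD,
            )
            == []
        )

    def test_provider_failure_degrades_to_empty(self):
        assert (
            collect_paraphrases(
                "what is the charge of benzene?", ["benzene"], _ExplodingProvider()
            )
            == []
        )


class TestAssembleDataset:
    def test_sizes_and_disjoint_splits(self, schema, store):
        examples, stats = assemble_dataset(
            schema,
            store,
            {"train": 12, "dev": 3, "test": 3},
            rng=random.Random(4),
        )
        assert stats.size == 18
        questions = [ex.question for ex in examples]
        assert len(set(questions)) == 18
        assert {ex.split for ex in examples} == {"train", "dev", "test"}

    def test_question_always_in_pool(self, gold_dataset):
        examples, _ = gold_dataset
        for ex in examples:
            assert ex.question in {ex.canonical_question, *ex.paraphrases}

    def test_byte_identical_for_same_seed(self, schema, store):
        a, _ = assemble_dataset(schema, store, {"train": 8}, rng=random.Random(9))
        b, _ = assemble_dataset(schema, store, {"train": 8}, rng=random.Random(9))
        assert a == b

    def test_grounded_surfaces_verbatim_in_question_and_query(self, gold_dataset):
        examples, _ = gold_dataset
        for ex in examples:
            sparql = decode(ex.encoded_query)
            for lit in re.findall(r'"((?:[^"\\]|\\.)*)"', sparql):
                assert lit in ex.canonical_question
                assert lit in sparql

    def test_every_query_parses_and_executes(self, gold_dataset, store):
        examples, _ = gold_dataset
        for ex in examples:
            sparql = decode(ex.encoded_query)
            parse_select(DEFAULT_PROLOGUE + "\n" + sparql)
            execute_select(store, sparql)  # no syntax error


class TestDatasetStatistics:
    def _example(self, n_relations, functions):
        return QAExample(
            question=f"q{n_relations}{functions}",
            encoded_query="SELECT var_x WHERE &lcub; &rcub;",
            canonical_question="q",
            paraphrases=(),
            split="train",
            metadata={"n_relations": n_relations, "functions": functions},
        )

    def test_relation_count_percentages(self):
        stats = dataset_statistics(
            [self._example(1, []), self._example(2, [])]
        )
        assert stats.pct_by_relation_count == {1: 50.0, 2: 50.0, 3: 0.0}
        assert sum(stats.pct_by_relation_count.values()) == pytest.approx(100)

    def test_function_occurrence_counted_per_example(self, gold_dataset):
        examples, _ = gold_dataset
        stats = dataset_statistics(examples)
        for op in OPERATORS:
            expected = 100.0 * sum(
                op in ex.metadata["functions"] for ex in examples
            ) / len(examples)
            assert stats.pct_function[op] == pytest.approx(expected)
        assert all(0 <= v <= 100 for v in stats.pct_function.values())
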