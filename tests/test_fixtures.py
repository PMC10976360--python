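import random

import pytest
import rdflib

from chemkgqa.codec import decode
from chemkgqa.fixtures import (
    CorruptionError,
    CorruptionSpec,
    FixtureConfig,
    PropertySpec,
    corrupt,
    generate_kg,
    make_gold_dataset,
)
from chemkgqa.kg import (
    OS,
    DEFAULT_PROLOGUE,
    SparqlSyntaxError,
    execute_select,
    parse_select,
)
from chemkgqa.pipeline import levenshtein, _literal_spans


class TestGenerateKG:
    def test_same_seed_byte_identical(self):
        a = generate_kg(FixtureConfig(n_species=5, seed=3))
        b = generate_kg(FixtureConfig(n_species=5, seed=3))
        assert a.ontology == b.ontology
        assert a.instances == b.instances

    def test_species_count(self):
        fkg = generate_kg(FixtureConfig(n_species=10, seed=1))
        rows = execute_select(
            fkg.store(), "SELECT ?s WHERE { ?s a os:Species . }"
        )
        assert len(rows) == 10

    def test_each_species_has_two_identifiers(self, store):
        rows = execute_select(
            store,
            "SELECT ?s ?i WHERE { ?s a os:Species . ?s ?p ?i . "
            "{ ?i a os:IUPACName . } UNION { ?i a os:SMILES . } }",
        )
        per_species = {}
        for row in rows:
            per_species.setdefault(row["s"], set()).add(row["i"])
        assert all(len(ids) >= 2 for ids in per_species.values())
        assert len(per_species) == 30  # default config

    def test_every_property_node_follows_reified_pattern(self, store):
        """Structural audit: every numeric property node must expose value
        and unit, and any reference state must itself carry value + unit."""
        dangling = execute_select(
            store,
            "SELECT ?o WHERE { ?s os:hasBoilingPoint|os:hasMeltingPoint|"
            "os:hasMolecularWeight|os:hasCharge|os:hasOpticalRotation ?o . "
            "FILTER NOT EXISTS { ?o os:value ?v . ?o os:unit ?u . } }",
        )
        assert dangling == []
        broken_ref = execute_select(
            store,
            "SELECT ?r WHERE { ?o os:hasReferenceState ?r . "
            "FILTER NOT EXISTS { ?r os:value ?v . ?r os:unit ?u . } }",
        )
        assert broken_ref == []

    def test_reference_states_present_but_optional(self, store):
        with_ref = execute_select(
            store, "SELECT ?o WHERE { ?o os:hasReferenceState ?r . }"
        )
        boiling = execute_select(
            store, "SELECT ?o WHERE { ?s os:hasBoilingPoint ?o . }"
        )
        assert 0 < len(with_ref)  # OPTIONAL block exercised...
        assert len(with_ref) < 5 * len(boiling)  # ...but not universal

    def test_round_trip_preserves_triple_count(self, fixture_kg, tmp_path):
        paths = fixture_kg.write(tmp_path)
        for path, text in zip(paths, (fixture_kg.ontology, fixture_kg.instances)):
            g = rdflib.Graph()
            g.parse(path)
            assert len(g) == len(text.strip().splitlines())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FixtureConfig(n_species=0)
        with pytest.raises(ValueError):
            PropertySpec("X", "x", 5.0, 5.0, "K")

    def test_smiles_strings_are_balanced_and_repetitive(self, store):
        rows = execute_select(
            store, "SELECT ?v WHERE { ?i a os:SMILES . ?i os:value ?v . }"
        )
        assert rows
        for row in rows:
            s = row["v"]
            assert s.count("(") == s.count(")")
            for digit in set(c for c in s if c.isdigit()):
                assert s.count(digit) % 2 == 0  # ring bonds open and close


class TestGoldDataset:
    def test_gold_map_injective_and_executable(self, schema, store):
        examples, gold_map = make_gold_dataset(schema, store, 20, seed=5)
        assert len(examples) == 20
        assert len(gold_map) == 20
        for encoded in gold_map.values():
            sparql = decode(encoded)
            parse_select(DEFAULT_PROLOGUE + "\n" + sparql)
            execute_select(store, sparql)

    def test_fixed_seed_reproducible(self, schema, store):
        a, _ = make_gold_dataset(schema, store, 10, seed=8)
        b, _ = make_gold_dataset(schema, store, 10, seed=8)
        assert a == b


class TestCorruptions:
    def _example_with(self, examples, predicate):
        for ex in examples:
            if predicate(decode(ex.encoded_query)):
                return ex
        pytest.fail("no suitable example in fixture dataset")

    def test_typo_magnitude_one_changes_literal_by_one_edit(
        self, schema, gold_dataset
    ):
        examples, _ = gold_dataset
        ex = self._example_with(examples, lambda q: '"' in q)
        before = [lit for _, _, lit in _literal_spans(decode(ex.encoded_query))]
        pred = corrupt(ex, CorruptionSpec("typo_in_literal", magnitude=1, seed=4), schema)
        after = [lit for _, _, lit in _literal_spans(decode(pred))]
        distances = sorted(levenshtein(a, b) for a, b in zip(before, after))
        assert distances[-1] == 1 and sum(distances) == 1

    def test_brace_break_fails_sparql_parse(self, schema, gold_dataset):
        examples, _ = gold_dataset
        pred = corrupt(examples[0], CorruptionSpec("brace_break"), schema)
        with pytest.raises(SparqlSyntaxError):
            parse_select(DEFAULT_PROLOGUE + "\n" + decode(pred))

    def test_function_flip_swaps_inside_for_outside(self, schema, gold_dataset):
        examples, _ = gold_dataset
        ex = self._example_with(examples, lambda q: "&&" in q)
        pred = decode(corrupt(ex, CorruptionSpec("function_flip"), schema))
        assert "||" in pred

    def test_relation_synonym_leaves_schema(self, schema, gold_dataset):
        examples, _ = gold_dataset
        ex = self._example_with(examples, lambda q: "os:has" in q)
        pred = decode(corrupt(ex, CorruptionSpec("relation_synonym"), schema))
        import re

        locals_ = set(re.findall(r"os:([A-Za-z_][A-Za-z0-9_]*)", pred))
        assert locals_ - {"value", "unit", "hasReferenceState"} - set(
            schema.relation_local_names
        )

    def test_inapplicable_mode_raises(self, schema, gold_dataset):
        examples, _ = gold_dataset
        ex = self._example_with(examples, lambda q: "FILTER" not in q)
        with pytest.raises(CorruptionError):
            corrupt(ex, CorruptionSpec("function_flip"), schema)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            CorruptionSpec("scramble_everything")
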