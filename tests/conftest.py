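import random

import pytest

from chemkgqa import fixtures
from chemkgqa.kg import KGStore, load_schema


@pytest.fixture(scope="session")
def fixture_kg():
    return fixtures.generate_kg()


@pytest.fixture(scope="session")
def schema(fixture_kg):
    return fixture_kg.schema()


@pytest.fixture(scope="session")
def store(fixture_kg):
    return fixture_kg.store()


@pytest.fixture(scope="session")
def gold_dataset(schema, store):
    """30 gold examples plus the question -> encoded-query map."""
    return fixtures.make_gold_dataset(schema, store, 30, seed=11)


@pytest.fixture(scope="session")
def kg_dir(tmp_path_factory, fixture_kg):
    out = tmp_path_factory.mktemp("kg")
    fixture_kg.write(out)
    return out


@pytest.fixture()
def rng():
    return random.Random(0)


TINY_ONTOLOGY = """\
@prefix os: <https://example.org/kb/ontospecies#> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .

os:Species a owl:Class ; rdfs:label "chemical species" .
os:BoilingPoint a owl:Class ; rdfs:label "boiling point" ;
    rdfs:subClassOf os:BoilingPointValueRestriction .
os:BoilingPointValueRestriction a owl:Restriction ;
    owl:onProperty os:value ; owl:someValuesFrom xsd:decimal .
os:Use a owl:Class ; rdfs:label "use" .

os:hasBoilingPoint a owl:ObjectProperty ; rdfs:label "boiling point" ;
    rdfs:domain os:Species ; rdfs:range os:BoilingPoint .
os:hasUse a owl:ObjectProperty ; rdfs:label "uses" ;
    rdfs:domain os:Species ; rdfs:range os:Use .
"""


@pytest.fixture()
def tiny_ontology(tmp_path):
    path = tmp_path / "tiny.ttl"
    path.write_text(TINY_ONTOLOGY)
    return path
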