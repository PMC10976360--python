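"""Ontology schema and knowledge-graph access.

The knowledge graphs targeted here follow the OntoSpecies modelling style:
chemical species nodes carry identifiers (IUPAC names, SMILES strings, ...)
as subclasses of an ``Identifier`` class, numeric properties are reified as
nodes holding a value, a unit and an optional reference state, and species
are annotated with chemical classes and uses.  This module loads such an
ontology into a lightweight :class:`OntologySchema` (the grammar that drives
question/query generation and relation correction) and wraps query execution
against either an in-memory rdflib graph or a remote SPARQL 1.1 endpoint.
"""

from __future__ import annotations

import decimal
import json
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import rdflib
from rdflib import OWL, RDF, RDFS, XSD
from rdflib.namespace import SKOS

__all__ = [
    "OS",
    "DEFAULT_PROLOGUE",
    "CORE_PREDICATES",
    "ClassDef",
    "RelationDef",
    "OntologySchema",
    "KGStore",
    "SchemaError",
    "SparqlSyntaxError",
    "EndpointError",
    "load_schema",
    "execute_select",
    "relations_from",
]

#: Namespace of the OntoSpecies-style ontology; bound to the ``os:`` prefix.
OS = rdflib.Namespace("https://example.org/kb/ontospecies#")

#: Prefix declarations injected before every executed query.  Dataset queries
#: themselves are stored without PREFIX lines to keep training strings short.
DEFAULT_PROLOGUE = (
    f"PREFIX os: <{OS}>\n"
    f"PREFIX rdfs: <{RDFS}>\n"
    f"PREFIX rdf: <{RDF}>\n"
    f"PREFIX xsd: <{XSD}>\n"
)

#: Structural predicates of the value/unit/reference-state reification
#: pattern.  They live in the ``os:`` namespace but are not schema relations,
#: so relation correction must never try to realign them.
CORE_PREDICATES = frozenset({"value", "unit", "hasReferenceState"})

_NUMERIC_DATATYPES = {XSD.decimal, XSD.integer, XSD.double, XSD.float}


class SchemaError(ValueError):
    """The ontology document violates the schema contract."""


class SparqlSyntaxError(ValueError):
    """A query failed SPARQL 1.1 parsing (distinct from an empty result)."""


class EndpointError(RuntimeError):
    """A remote SPARQL endpoint could not be reached or answered badly."""


@dataclass(frozen=True)
class ClassDef:
    """An ontology class: IRI, human label and optional single parent."""

    iri: str
    label: str
    parent: str | None = None

    @property
    def local_name(self) -> str:
        return _local(self.iri)


@dataclass(frozen=True)
class RelationDef:
    """A relation (object property) between two ontology classes.

    ``numeric`` is true when the range class reifies a numeric quantity,
    i.e. instances carry an ``os:value`` literal typed decimal/integer.
    """

    iri: str
    label: str
    domain: str
    range: str
    numeric: bool = False
    surface_forms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.label:
            raise SchemaError(f"relation {self.iri} has an empty label")
        if self.label not in self.surface_forms:
            object.__setattr__(
                self, "surface_forms", (self.label, *self.surface_forms)
            )

    @property
    def local_name(self) -> str:
        return _local(self.iri)

    @property
    def qname(self) -> str:
        """Compact ``os:localName`` form used in dataset queries."""
        return f"os:{self.local_name}"


@dataclass(frozen=True)
class OntologySchema:
    """All classes and relations of the ontology, plus the special roles
    (species class, identifier subclasses) that the query grammar needs."""

    classes: tuple[ClassDef, ...]
    relations: tuple[RelationDef, ...]
    species_class: str
    identifier_classes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        class_iris = {c.iri for c in self.classes}
        if len(class_iris) != len(self.classes):
            raise SchemaError("duplicate class IRIs in schema")
        rel_iris = [r.iri for r in self.relations]
        if len(set(rel_iris)) != len(rel_iris):
            raise SchemaError("duplicate relation IRIs in schema")
        for c in self.classes:
            if c.parent is not None and c.parent not in class_iris:
                raise SchemaError(
                    f"class {c.iri} has undeclared parent {c.parent}"
                )
        for r in self.relations:
            if r.domain not in class_iris:
                raise SchemaError(
                    f"relation {r.iri} has undeclared domain {r.domain}"
                )
            if r.range not in class_iris:
                raise SchemaError(
                    f"relation {r.iri} has undeclared range {r.range}"
                )
        if self.species_class not in class_iris:
            raise SchemaError("species class is not declared in the schema")
        for iri in self.identifier_classes:
            if iri not in class_iris:
                raise SchemaError(f"identifier class {iri} not declared")

    # -- lookups -----------------------------------------------------------

    def class_by_iri(self, iri: str) -> ClassDef:
        for c in self.classes:
            if c.iri == iri:
                return c
        raise SchemaError(f"unknown class {iri}")

    def relation_by_local_name(self, local: str) -> RelationDef | None:
        for r in self.relations:
            if r.local_name == local:
                return r
        return None

    @property
    def relation_local_names(self) -> frozenset[str]:
        return frozenset(r.local_name for r in self.relations)

    def is_identifier_relation(self, rel: RelationDef) -> bool:
        return rel.range in self.identifier_classes


def _local(iri: str) -> str:
    """Local name of an IRI (after the last ``#`` or ``/``)."""
    for sep in ("#", "/"):
        if sep in iri:
            iri = iri.rsplit(sep, 1)[1]
    return iri


def load_schema(
    path: str | Path | rdflib.Graph,
    *,
    species_local_name: str = "Species",
    identifier_local_name: str = "Identifier",
    numeric_overrides: Mapping[str, bool] | None = None,
    identifier_classes: Iterable[str] | None = None,
) -> OntologySchema:
    """Load an :class:`OntologySchema` from an ontology document.

    Classes are ``owl:Class`` nodes; relations are ``owl:ObjectProperty``
    nodes with ``rdfs:domain``/``rdfs:range``.  A relation counts as numeric
    when its range class carries an OWL restriction stating that ``os:value``
    takes a decimal/integer literal; ``numeric_overrides`` (keyed by relation
    IRI or local name) takes precedence.  Identifier subclasses are derived
    from the class hierarchy under ``Identifier`` unless given explicitly.
    """
    if isinstance(path, rdflib.Graph):
        g = path
    else:
        g = rdflib.Graph()
        try:
            g.parse(str(path))
        except Exception as exc:  # rdflib raises many parser exceptions
            raise SchemaError(f"cannot parse ontology document {path}: {exc}")

    classes: dict[str, ClassDef] = {}
    for c in sorted(set(g.subjects(RDF.type, OWL.Class))):
        if not isinstance(c, rdflib.URIRef):
            continue
        label = str(g.value(c, RDFS.label) or _local(c))
        parent = None
        for p in sorted(g.objects(c, RDFS.subClassOf)):
            # restriction nodes mark numeric value ranges, not ancestry
            if isinstance(p, rdflib.URIRef) and (p, RDF.type, OWL.Restriction) not in g:
                parent = str(p)
                break  # single inheritance only
        classes[str(c)] = ClassDef(iri=str(c), label=label, parent=parent)
    if not classes:
        raise SchemaError("no classes found in ontology document")

    numeric_ranges = _numeric_range_classes(g)
    overrides = dict(numeric_overrides or {})

    relations: list[RelationDef] = []
    for r in sorted(set(g.subjects(RDF.type, OWL.ObjectProperty))):
        if not isinstance(r, rdflib.URIRef):
            continue
        iri = str(r)
        domain = g.value(r, RDFS.domain)
        rng = g.value(r, RDFS.range)
        if domain is None or rng is None:
            raise SchemaError(f"relation {iri} lacks a domain or range")
        if str(domain) not in classes:
            raise SchemaError(
                f"relation {iri} has domain {domain} which is not a declared class"
            )
        if str(rng) not in classes:
            raise SchemaError(
                f"relation {iri} has range {rng} which is not a declared class"
            )
        label = str(g.value(r, RDFS.label) or _decamel(_local(iri)))
        alts = tuple(sorted(str(a) for a in g.objects(r, SKOS.altLabel)))
        numeric = str(rng) in numeric_ranges
        if iri in overrides:
            numeric = bool(overrides[iri])
        elif _local(iri) in overrides:
            numeric = bool(overrides[_local(iri)])
        relations.append(
            RelationDef(
                iri=iri,
                label=label,
                domain=str(domain),
                range=str(rng),
                numeric=numeric,
                surface_forms=(label, *alts),
            )
        )

    species = None
    identifier_root = None
    for iri in classes:
        if _local(iri) == species_local_name:
            species = iri
        if _local(iri) == identifier_local_name:
            identifier_root = iri
    if species is None:
        raise SchemaError(
            f"ontology declares no class named {species_local_name!r}"
        )

    if identifier_classes is not None:
        ident = frozenset(identifier_classes)
    elif identifier_root is not None:
        ident = frozenset(
            iri
            for iri, c in classes.items()
            if _is_descendant(classes, iri, identifier_root)
        )
    else:
        ident = frozenset()

    return OntologySchema(
        classes=tuple(classes[i] for i in sorted(classes)),
        relations=tuple(sorted(relations, key=lambda r: r.iri)),
        species_class=species,
        identifier_classes=ident,
    )


def _numeric_range_classes(g: rdflib.Graph) -> set[str]:
    """Classes restricted so that ``os:value`` yields a numeric literal."""
    out: set[str] = set()
    for restr in g.subjects(OWL.onProperty, OS.value):
        if g.value(restr, OWL.someValuesFrom) in _NUMERIC_DATATYPES:
            for cls in g.subjects(RDFS.subClassOf, restr):
                if isinstance(cls, rdflib.URIRef):
                    out.add(str(cls))
    return out


def _is_descendant(
    classes: Mapping[str, ClassDef], iri: str, ancestor: str
) -> bool:
    seen = set()
    cur: str | None = iri
    while cur is not None and cur not in seen:
        seen.add(cur)
        parent = classes[cur].parent if cur in classes else None
        if parent == ancestor:
            return True
        cur = parent
    return False


def _decamel(name: str) -> str:
    """``hasBoilingPt`` -> ``has boiling pt``."""
    out: list[str] = []
    for ch in name:
        if ch.isupper() and out and out[-1] != " ":
            out.append(" ")
        out.append(ch.lower())
    return "".join(out).replace("_", " ").strip()


# ---------------------------------------------------------------------------
# Query execution


class KGStore:
    """A queryable triple store: in-memory rdflib graph or remote endpoint.

    ``source`` may be an ``rdflib.Graph``, a path to a Turtle/N-Triples
    file, or an ``http(s)://`` SPARQL endpoint URL.  ``prologue`` holds the
    prefix declarations injected verbatim before every query, so dataset
    queries can omit PREFIX lines.
    """

    def __init__(
        self,
        source: str | Path | rdflib.Graph,
        prologue: str = DEFAULT_PROLOGUE,
    ) -> None:
        self.prologue = prologue
        self.endpoint: str | None = None
        self.graph: rdflib.Graph | None = None
        if isinstance(source, rdflib.Graph):
            self.graph = source
        elif isinstance(source, str) and source.startswith(("http://", "https://")):
            self.endpoint = source
        else:
            self.graph = rdflib.Graph()
            try:
                self.graph.parse(str(source))
            except Exception as exc:
                raise SchemaError(f"cannot parse instance file {source}: {exc}")

    def __len__(self) -> int:
        return len(self.graph) if self.graph is not None else 0

    def select(self, query: str) -> list[dict[str, object]]:
        """Run a SELECT query and return sorted rows of variable bindings.

        An empty table is a valid outcome (an answerable question about an
        absent entity yields a valid query and an empty response); a syntax
        error raises :class:`SparqlSyntaxError` instead.
        """
        full = self.prologue + "\n" + query
        parsed = parse_select(full)
        if self.endpoint is not None:
            return self._select_remote(full)
        assert self.graph is not None
        result = self.graph.query(parsed)
        rows = []
        for binding in result:
            row: dict[str, object] = {}
            for var, term in zip(result.vars, binding):
                if term is None:
                    continue
                row[str(var)] = _term_value(term)
            rows.append(row)
        rows.sort(key=lambda r: sorted((k, str(v)) for k, v in r.items()))
        return rows

    def _select_remote(self, full_query: str) -> list[dict[str, object]]:
        data = urllib.parse.urlencode({"query": full_query}).encode()
        req = urllib.request.Request(
            self.endpoint,  # type: ignore[arg-type]
            data=data,
            headers={
                "Accept": "application/sparql-results+json",
                "Content-Type": "application/x-www-form-urlencoded",
            },
        )
        try:
            with urllib.request.urlopen(req, timeout=30) as resp:
                payload = json.load(resp)
        except Exception as exc:
            raise EndpointError(f"endpoint {self.endpoint} unreachable: {exc}")
        rows = []
        for b in payload.get("results", {}).get("bindings", []):
            row = {}
            for var, cell in b.items():
                value = cell.get("value")
                if cell.get("type") == "literal":
                    dt = cell.get("datatype", "")
                    if dt and _local(dt) in {"decimal", "integer", "double", "float"}:
                        value = float(value)
                row[var] = value
            rows.append(row)
        rows.sort(key=lambda r: sorted((k, str(v)) for k, v in r.items()))
        return rows


def _term_value(term: rdflib.term.Node) -> object:
    if isinstance(term, rdflib.Literal):
        v = term.toPython()
        # normalise all numerics to float so oracle comparisons are stable
        if isinstance(v, (int, float, decimal.Decimal)) and not isinstance(v, bool):
            return float(v)
        return str(v)
    return str(term)


def parse_select(query: str):
    """Parse a SELECT query, raising :class:`SparqlSyntaxError` on failure."""
    from rdflib.plugins.sparql import prepareQuery

    try:
        return prepareQuery(query)
    except Exception as exc:
        raise SparqlSyntaxError(str(exc))


def execute_select(store: KGStore, query: str) -> list[dict[str, object]]:
    """Execute ``query`` (prologue injected) and return the result table."""
    return store.select(query)


def relations_from(schema: OntologySchema, cls: str) -> list[RelationDef]:
    """All relations whose domain is ``cls``, sorted by IRI (stable order)."""
    if cls not in {c.iri for c in schema.classes}:
        raise SchemaError(f"unknown class {cls}")
    return sorted(
        (r for r in schema.relations if r.domain == cls), key=lambda r: r.iri
    )


def decamel(name: str) -> str:
    """Public alias of the camel-case splitter used for relation surface
    normalisation (``hasBoilingPt`` -> ``has boiling pt``)."""
    return _decamel(name)
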