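"""Question/SPARQL dataset generation from an ontology and its instances.

The construction pipeline mirrors how KGQA training corpora are built from
a schema: (1) sample a subgraph of the ontology rooted at the species
class, (2) ground some of its nodes against the instance data and attach
comparative filters to numeric qualifiers, yielding a canonical logical
form, (3) verbalize the logical form into a canonical question, (4)
paraphrase it while preserving entity mentions verbatim, and (5) sample
the final question from the pool of canonical question plus accepted
paraphrases.

Three query intents are covered:

* ``property_lookup`` — one-hop queries about a given species
  ("what is the charge of benzene?"),
* ``species_search`` — queries for species satisfying constraints on
  their properties and uses,
* ``class_property`` — two-hop queries about properties of the members
  of a chemical class.

Entity linking is performed inside the query itself: species are matched
by exact string comparison against any of their identifier values via a
``VALUES`` binding, so queries carry surface forms instead of entity IRIs.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

from .codec import encode
from .kg import (
    KGStore,
    OntologySchema,
    RelationDef,
    SchemaError,
    execute_select,
    parse_select,
    relations_from,
)

__all__ = [
    "OPERATORS",
    "QueryIntent",
    "VerbalizationForm",
    "ComparativeFilter",
    "SchemaSubgraph",
    "CanonicalQuery",
    "QAExample",
    "DatasetStats",
    "GeneratorConfig",
    "GenerationError",
    "ParaphraseProvider",
    "RuleBasedParaphraser",
    "format_number",
    "build_filter",
    "build_species_grounding",
    "sample_subgraph",
    "ground_query",
    "verbalize",
    "collect_paraphrases",
    "assemble_dataset",
    "dataset_statistics",
    "write_jsonl",
    "read_jsonl",
]

#: The five comparative operators applied to numeric qualifiers.
OPERATORS = ("higher", "lower", "inside", "outside", "around")


class GenerationError(RuntimeError):
    """Dataset generation failed (incompatible intent, no instances, ...)."""


class QueryIntent(str, Enum):
    PROPERTY_LOOKUP = "property_lookup"
    SPECIES_SEARCH = "species_search"
    CLASS_PROPERTY = "class_property"


class VerbalizationForm(str, Enum):
    INTERROGATIVE = "interrogative"
    IMPERATIVE = "imperative"
    KEYWORD = "keyword"


def format_number(x: float) -> str:
    """Render a number compactly: trailing zeros trimmed, ``.`` separator."""
    if float(x) == int(x):
        return str(int(x))
    return f"{float(x):.12g}"


@dataclass(frozen=True)
class ComparativeFilter:
    """A numeric constraint on a query variable ``x``.

    Logical forms: higher ``x > a``; lower ``x < a``; inside
    ``a < x < b``; outside ``x < a || x > b``; around ``0.9a < x < 1.1a``
    (defined for ``a > 0`` only).  ``a`` and ``b`` are stored in user
    order; the realized bounds are normalized so the smaller one is the
    lower bound.
    """

    op: str
    variable: str
    a: float
    b: float | None = None

    def __post_init__(self) -> None:
        if self.op not in OPERATORS:
            raise ValueError(f"unknown comparative operator {self.op!r}")
        needs_b = self.op in ("inside", "outside")
        if needs_b and self.b is None:
            raise ValueError(f"operator {self.op!r} requires both bounds")
        if not needs_b and self.b is not None:
            raise ValueError(f"operator {self.op!r} takes a single threshold")
        if self.op == "around" and not self.a > 0:
            raise ValueError("'around' is defined for a > 0 only")

    def bounds(self) -> tuple[float, float] | None:
        """Normalized (lower, upper) for two-sided operators, else None."""
        if self.op in ("inside", "outside"):
            assert self.b is not None
            return (min(self.a, self.b), max(self.a, self.b))
        if self.op == "around":
            return (0.9 * self.a, 1.1 * self.a)
        return None

    def matches(self, x: float) -> bool:
        """Whether a value satisfies the constraint (strict comparisons)."""
        if self.op == "higher":
            return x > self.a
        if self.op == "lower":
            return x < self.a
        lo, hi = self.bounds()  # type: ignore[misc]
        if self.op == "outside":
            return x < lo or x > hi
        return lo < x < hi


def build_filter(f: ComparativeFilter) -> str:
    """Realize a :class:`ComparativeFilter` as a SPARQL FILTER clause."""
    v = f"?{f.variable}"
    if f.op == "higher":
        return f"FILTER ({v} > {format_number(f.a)})"
    if f.op == "lower":
        return f"FILTER ({v} < {format_number(f.a)})"
    lo, hi = f.bounds()  # type: ignore[misc]
    lo_s, hi_s = format_number(lo), format_number(hi)
    if f.op == "outside":
        return f"FILTER ({v} < {lo_s} || {v} > {hi_s})"
    return f"FILTER ({lo_s} < {v} && {v} < {hi_s})"


def _escape_literal(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def build_species_grounding(surface: str) -> str:
    """Triple-pattern block linking the species node by exact identifier
    match: a ``VALUES`` binding of the surface form plus patterns matching
    any identifier whose value equals it."""
    if not surface:
        raise ValueError("empty species surface form")
    lit = _escape_literal(surface)
    return (
        f'VALUES (?species) {{ ("{lit}") }}\n'
        "?SpeciesIRI ?hasIdentifier ?IdentifierIRI .\n"
        "?IdentifierIRI os:value ?species ."
    )


# ---------------------------------------------------------------------------
# Schema subgraphs


@dataclass(frozen=True)
class SchemaSubgraph:
    """An ungrounded subgraph: the species class and 1–3 outgoing edges."""

    root: str
    edges: tuple[tuple[RelationDef, str], ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.edges) <= 3:
            raise ValueError("subgraph out-degree must lie in [1, 3]")
        for rel, target in self.edges:
            if rel.domain != self.root:
                raise ValueError(f"edge {rel.iri} does not start at the root")
            if rel.range != target:
                raise ValueError(f"edge {rel.iri} target mismatch")

    @property
    def out_degree(self) -> int:
        return len(self.edges)


def sample_subgraph(
    schema: OntologySchema,
    out_degree: int,
    rng: random.Random,
    *,
    include_identifier_edges: bool = False,
) -> SchemaSubgraph:
    """Sample ``out_degree`` distinct edges from the species class.

    Identifier-typed relations are excluded by default: species grounding
    already matches identifiers through the VALUES block, so sampling them
    as content edges would duplicate that role.
    """
    if not 1 <= out_degree <= 3:
        raise ValueError("out_degree must lie in [1, 3]")
    candidates = [
        r
        for r in relations_from(schema, schema.species_class)
        if include_identifier_edges or not schema.is_identifier_relation(r)
    ]
    if len(candidates) < out_degree:
        raise GenerationError(
            f"schema offers only {len(candidates)} species relations, "
            f"cannot sample {out_degree}"
        )
    edges = tuple((r, r.range) for r in rng.sample(candidates, out_degree))
    return SchemaSubgraph(root=schema.species_class, edges=edges)


# ---------------------------------------------------------------------------
# Canonical queries


@dataclass(frozen=True)
class Criterion:
    """One species-search constraint, kept for verbalization."""

    kind: str  # "use" | "class" | "numeric"
    label: str
    literal: str | None = None
    filter: ComparativeFilter | None = None


@dataclass(frozen=True)
class QuerySlots:
    """Verbalization payload of a canonical query."""

    question_labels: tuple[str, ...] = ()
    species_surface: str | None = None
    class_surface: str | None = None
    criteria: tuple[Criterion, ...] = ()


@dataclass(frozen=True)
class CanonicalQuery:
    sparql: str
    intent: QueryIntent
    relations: tuple[str, ...]
    filters: tuple[ComparativeFilter, ...]
    groundings: tuple[tuple[str, str], ...]
    slots: QuerySlots = field(default_factory=QuerySlots)

    @property
    def n_relations(self) -> int:
        return len(self.relations)

    def validate(self, prologue: str) -> None:
        parse_select(prologue + "\n" + self.sparql)
        for f in self.filters:
            if f"?{f.variable}" not in self.sparql:
                raise ValueError(f"filter variable ?{f.variable} unused")


def _var_base(rel: RelationDef) -> str:
    local = rel.local_name
    return local[3:] if local.startswith("has") else local[:1].upper() + local[1:]


def _edge_kind(schema: OntologySchema, rel: RelationDef) -> str:
    if rel.numeric:
        return "numeric"
    local = rel.range.rsplit("#", 1)[-1].rsplit("/", 1)[-1]
    if local == "ChemicalClass":
        return "class"
    if schema.is_identifier_relation(rel):
        return "identifier"
    return "use"


def _pick(rng: random.Random, items: Sequence) -> object:
    if not items:
        raise GenerationError("knowledge graph lacks instances to ground")
    return items[rng.randrange(len(items))]


def _species_with_edges(
    kg: KGStore, edges: Sequence[tuple[RelationDef, str]], rng: random.Random
) -> str:
    patterns = " ".join(f"?s <{rel.iri}> ?o{i} ." for i, (rel, _) in enumerate(edges))
    rows = execute_select(kg, f"SELECT DISTINCT ?s WHERE {{ {patterns} }}")
    return str(_pick(rng, [r["s"] for r in rows]))


def _node_values(kg: KGStore, species: str, rel: RelationDef) -> list:
    rows = execute_select(
        kg,
        f"SELECT ?v WHERE {{ <{species}> <{rel.iri}> ?o . ?o os:value ?v . }}",
    )
    return [r["v"] for r in rows]


def _identifier_values(kg: KGStore, species: str, schema: OntologySchema) -> list[str]:
    values: list[str] = []
    for cls in sorted(schema.identifier_classes):
        rows = execute_select(
            kg,
            f"SELECT ?v WHERE {{ <{species}> ?p ?i . "
            f"?i a <{cls}> . ?i os:value ?v . }}",
        )
        values.extend(str(r["v"]) for r in rows)
    return values


def _satisfying_filter(
    var: str, v: float, rng: random.Random, operators: Sequence[str] = OPERATORS
) -> ComparativeFilter:
    """Draw an operator uniformly and bounds such that ``v`` satisfies it.

    ``around`` requires a positive threshold, so for non-positive values
    the draw falls back to the remaining four operators.
    """
    ops = list(operators)
    if v <= 0 and "around" in ops:
        ops.remove("around")
    op = str(_pick(rng, ops))
    spread = max(1.0, abs(v) * 0.2)
    if op == "higher":
        return ComparativeFilter(op, var, a=v - spread * rng.uniform(0.5, 1.5))
    if op == "lower":
        return ComparativeFilter(op, var, a=v + spread * rng.uniform(0.5, 1.5))
    if op == "around":
        return ComparativeFilter(op, var, a=v)
    if op == "inside":
        lo = v - spread * rng.uniform(0.5, 1.5)
        hi = v + spread * rng.uniform(0.5, 1.5)
    else:  # outside: an interval strictly on one side of v
        if rng.random() < 0.5:
            hi = v - spread * rng.uniform(0.1, 0.5)
            lo = hi - spread * rng.uniform(0.5, 1.5)
        else:
            lo = v + spread * rng.uniform(0.1, 0.5)
            hi = lo + spread * rng.uniform(0.5, 1.5)
    a, b = (lo, hi) if rng.random() < 0.5 else (hi, lo)  # user order unordered
    return ComparativeFilter(op, var, a=a, b=b)


def ground_query(
    sub: SchemaSubgraph,
    intent: QueryIntent,
    kg: KGStore,
    rng: random.Random,
    schema: OntologySchema,
    operators: Sequence[str] = OPERATORS,
) -> CanonicalQuery:
    """Ground a schema subgraph into a canonical SPARQL logical form.

    Groundings are drawn from the instance data so that the query has at
    least one answer.  Every numeric qualifier of a species search receives
    exactly one comparative filter with the operator drawn uniformly.
    """
    intent = QueryIntent(intent)
    kinds = [_edge_kind(schema, rel) for rel, _ in sub.edges]
    if "identifier" in kinds:
        raise GenerationError("identifier edges cannot be grounded as content")

    if intent is QueryIntent.CLASS_PROPERTY:
        if "class" not in kinds or len(sub.edges) < 2:
            raise GenerationError(
                "class_property needs a chemical-class edge plus a question edge"
            )
        return _ground_class_property(sub, kinds, kg, rng, schema)
    if intent is QueryIntent.SPECIES_SEARCH:
        return _ground_species_search(sub, kinds, kg, rng, schema, operators)
    return _ground_property_lookup(sub, kg, rng, schema)


def _ground_property_lookup(sub, kg, rng, schema) -> CanonicalQuery:
    species = _species_with_edges(kg, sub.edges, rng)
    idents = _identifier_values(kg, species, schema)
    surface = str(_pick(rng, idents))
    select_vars, body = [], [build_species_grounding(surface)]
    labels = []
    for rel, _ in sub.edges:
        base = _var_base(rel)
        body.append(f"?SpeciesIRI {rel.qname} ?{base}IRI .")
        body.append(f"?{base}IRI os:value ?{base}Value .")
        select_vars.append(f"?{base}Value")
        labels.append(rel.label)
    sparql = _assemble_sparql(select_vars, body)
    return CanonicalQuery(
        sparql=sparql,
        intent=QueryIntent.PROPERTY_LOOKUP,
        relations=tuple(rel.iri for rel, _ in sub.edges),
        filters=(),
        groundings=(("species", surface),),
        slots=QuerySlots(question_labels=tuple(labels), species_surface=surface),
    )


def _ground_species_search(sub, kinds, kg, rng, schema, operators) -> CanonicalQuery:
    species = _species_with_edges(kg, sub.edges, rng)
    select_vars = ["?SpeciesIRI"]
    body: list[str] = []
    filters: list[ComparativeFilter] = []
    groundings: list[tuple[str, str]] = []
    criteria: list[Criterion] = []
    filter_lines: list[str] = []
    for (rel, _), kind in zip(sub.edges, kinds):
        base = _var_base(rel)
        body.append(f"?SpeciesIRI {rel.qname} ?{base}IRI .")
        if kind == "numeric":
            var = f"{base}Value"
            body.append(f"?{base}IRI os:value ?{var} .")
            select_vars.append(f"?{var}")
            v = float(_pick(rng, _node_values(kg, species, rel)))
            f = _satisfying_filter(var, v, rng, operators)
            filters.append(f)
            filter_lines.append(build_filter(f))
            criteria.append(Criterion("numeric", rel.label, filter=f))
        else:
            literal = str(_pick(rng, _node_values(kg, species, rel)))
            body.append(f'?{base}IRI os:value "{_escape_literal(literal)}" .')
            groundings.append((rel.label, literal))
            criteria.append(Criterion(kind, rel.label, literal=literal))
    sparql = _assemble_sparql(select_vars, body + filter_lines)
    return CanonicalQuery(
        sparql=sparql,
        intent=QueryIntent.SPECIES_SEARCH,
        relations=tuple(rel.iri for rel, _ in sub.edges),
        filters=tuple(filters),
        groundings=tuple(groundings),
        slots=QuerySlots(criteria=tuple(criteria)),
    )


def _ground_class_property(sub, kinds, kg, rng, schema) -> CanonicalQuery:
    class_idx = kinds.index("class")
    class_rel = sub.edges[class_idx][0]
    species = _species_with_edges(kg, sub.edges, rng)
    class_literal = str(_pick(rng, _node_values(kg, species, class_rel)))
    base = _var_base(class_rel)
    body = [
        f"?SpeciesIRI {class_rel.qname} ?{base}IRI .",
        f'?{base}IRI os:value "{_escape_literal(class_literal)}" .',
    ]
    select_vars = ["?SpeciesIRI"]
    labels = []
    for i, (rel, _) in enumerate(sub.edges):
        if i == class_idx:
            continue
        b = _var_base(rel)
        body.append(f"?SpeciesIRI {rel.qname} ?{b}IRI .")
        body.append(f"?{b}IRI os:value ?{b}Value .")
        select_vars.append(f"?{b}Value")
        labels.append(rel.label)
    sparql = _assemble_sparql(select_vars, body)
    return CanonicalQuery(
        sparql=sparql,
        intent=QueryIntent.CLASS_PROPERTY,
        relations=tuple(rel.iri for rel, _ in sub.edges),
        filters=(),
        groundings=((class_rel.label, class_literal),),
        slots=QuerySlots(
            question_labels=tuple(labels), class_surface=class_literal
        ),
    )


def _assemble_sparql(select_vars: Sequence[str], body: Sequence[str]) -> str:
    lines = [f"SELECT {' '.join(select_vars)}", "WHERE {"]
    for item in body:
        lines.extend(item.split("\n"))
    lines.append("}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Verbalization

DEFAULT_TEMPLATES: dict = {
    "property_lookup": {
        "interrogative": "what {be} the {props} of {species}?",
        "imperative": "tell me about the {props} of {species}.",
        "keyword": "{props} of {species}",
    },
    "species_search": {
        "interrogative": "what are the chemical species that {criteria}?",
        "imperative": "find chemical species that {criteria}.",
        "keyword": "chemical species that {criteria}",
    },
    "class_property": {
        "interrogative": "what {be} the {props} of chemical species classified as {cls}?",
        "imperative": "tell me about the {props} of chemical species classified as {cls}.",
        "keyword": "{props} of chemical species classified as {cls}",
    },
    "operators": {
        "higher": "higher than {a}",
        "lower": "lower than {a}",
        "inside": "inside the range between {a} and {b}",
        "outside": "outside the range between {a} and {b}",
        "around": "around {a}",
    },
    "criteria": {
        "use": "can be used as a {value}",
        "class": "are classified as {value}",
        "numeric": "have a {label} {op}",
    },
}


def verbalize(
    q: CanonicalQuery,
    form: VerbalizationForm,
    templates: Mapping = DEFAULT_TEMPLATES,
) -> str:
    """Deterministic template realization of a canonical query.

    Entity surface forms appear verbatim; numeric filters are verbalized
    with their operator phrase ("higher than a", "around a", ...), with
    two-sided bounds printed in the user-supplied (possibly unordered)
    order.
    """
    form = VerbalizationForm(form)
    intent_templates = templates[q.intent.value]
    if q.intent is QueryIntent.SPECIES_SEARCH:
        phrases = []
        for c in q.slots.criteria:
            if c.kind == "numeric":
                f = c.filter
                assert f is not None
                op_phrase = templates["operators"][f.op].format(
                    a=format_number(f.a),
                    b=format_number(f.b) if f.b is not None else "",
                )
                phrases.append(
                    templates["criteria"]["numeric"].format(
                        label=c.label, op=op_phrase
                    )
                )
            else:
                phrases.append(
                    templates["criteria"][c.kind].format(value=c.literal)
                )
        return intent_templates[form.value].format(criteria=" and ".join(phrases))
    props = " and ".join(q.slots.question_labels)
    be = "is" if len(q.slots.question_labels) == 1 else "are"
    if q.intent is QueryIntent.PROPERTY_LOOKUP:
        return intent_templates[form.value].format(
            be=be, props=props, species=q.slots.species_surface
        )
    return intent_templates[form.value].format(
        be=be, props=props, cls=q.slots.class_surface
    )


# ---------------------------------------------------------------------------
# Paraphrasing


class ParaphraseProvider(Protocol):
    """Produces candidate rephrasings of a question."""

    def paraphrase(self, question: str, n: int) -> list[str]: ...


class RuleBasedParaphraser:
    """Deterministic rule-based rewriter used as the default provider.

    Each rewrite rule substitutes a relation- or template-side phrase;
    entity mentions are never touched, so candidates pass the
    entity-preservation filter by construction.  A remote LLM provider can
    be plugged in through the same protocol.
    """

    RULES: tuple[tuple[str, str], ...] = (
        ("what is the ", "what's the "),
        ("what is the ", "i would like to know the "),
        ("what are the chemical species that ", "which chemical species "),
        ("what are the ", "could you list the "),
        ("tell me about the ", "show me the "),
        ("tell me about the ", "provide the "),
        ("find chemical species that ", "search for chemical species that "),
        ("chemical species", "compounds"),
        ("boiling point", "boiling temperature"),
        ("melting point", "melting temperature"),
    )

    def paraphrase(self, question: str, n: int) -> list[str]:
        out: list[str] = []
        for src, dst in self.RULES:
            if src in question:
                cand = question.replace(src, dst, 1)
                if cand != question and cand not in out:
                    out.append(cand)
            if len(out) >= n:
                break
        return out[:n]


def collect_paraphrases(
    canonical: str,
    entities: Sequence[str],
    provider: ParaphraseProvider,
    n: int = 5,
    form: VerbalizationForm = VerbalizationForm.INTERROGATIVE,
) -> list[str]:
    """Gather up to ``n`` paraphrases, keeping only those that preserve
    every entity mention verbatim.  Keyword-form questions are never
    paraphrased.  Provider failure degrades to an empty list — the
    canonical question remains usable."""
    if VerbalizationForm(form) is VerbalizationForm.KEYWORD:
        return []
    try:
        candidates = provider.paraphrase(canonical, n)
    except Exception:
        return []
    accepted = []
    for cand in candidates[:n]:
        if cand != canonical and all(e in cand for e in entities):
            accepted.append(cand)
    return accepted


# ---------------------------------------------------------------------------
# Dataset assembly


@dataclass(frozen=True)
class QAExample:
    question: str
    encoded_query: str
    canonical_question: str
    paraphrases: tuple[str, ...]
    split: str
    metadata: Mapping

    def to_dict(self) -> dict:
        return {
            "question": self.question,
            "encoded_query": self.encoded_query,
            "canonical_question": self.canonical_question,
            "paraphrases": list(self.paraphrases),
            "split": self.split,
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "QAExample":
        return cls(
            question=d["question"],
            encoded_query=d["encoded_query"],
            canonical_question=d["canonical_question"],
            paraphrases=tuple(d.get("paraphrases", ())),
            split=d.get("split", "train"),
            metadata=dict(d.get("metadata", {})),
        )


@dataclass(frozen=True)
class DatasetStats:
    size: int
    pct_by_relation_count: Mapping[int, float]
    pct_function: Mapping[str, float]

    def to_dict(self) -> dict:
        return {
            "size": self.size,
            "pct_by_relation_count": {
                str(k): v for k, v in self.pct_by_relation_count.items()
            },
            "pct_function": dict(self.pct_function),
        }


@dataclass
class GeneratorConfig:
    operators: tuple[str, ...] = OPERATORS
    intents: tuple[QueryIntent, ...] = (
        QueryIntent.PROPERTY_LOOKUP,
        QueryIntent.SPECIES_SEARCH,
        QueryIntent.CLASS_PROPERTY,
    )
    forms: tuple[VerbalizationForm, ...] = (
        VerbalizationForm.INTERROGATIVE,
        VerbalizationForm.IMPERATIVE,
        VerbalizationForm.KEYWORD,
    )
    n_paraphrases: int = 5
    paraphrase_provider: ParaphraseProvider = field(
        default_factory=RuleBasedParaphraser
    )
    include_identifier_edges: bool = False
    templates: Mapping = field(default_factory=lambda: DEFAULT_TEMPLATES)


def _sample_compatible(
    schema: OntologySchema,
    intent: QueryIntent,
    rng: random.Random,
    cfg: GeneratorConfig,
) -> SchemaSubgraph:
    """Sample a subgraph compatible with ``intent`` (uniform out-degree)."""
    lo = 2 if intent is QueryIntent.CLASS_PROPERTY else 1
    out_degree = rng.randint(lo, 3)
    for _ in range(50):
        sub = sample_subgraph(
            schema,
            out_degree,
            rng,
            include_identifier_edges=cfg.include_identifier_edges,
        )
        kinds = [_edge_kind(schema, rel) for rel, _ in sub.edges]
        if intent is QueryIntent.CLASS_PROPERTY and "class" not in kinds:
            continue
        return sub
    raise GenerationError(f"cannot sample a subgraph compatible with {intent}")


def _entities(q: CanonicalQuery) -> list[str]:
    return [literal for _, literal in q.groundings]


def make_example(
    schema: OntologySchema,
    kg: KGStore,
    rng: random.Random,
    cfg: GeneratorConfig,
    split: str,
) -> QAExample:
    """Generate one QA example end to end (subgraph → grounding →
    verbalization → paraphrases → final question sampling)."""
    intent = QueryIntent(_pick(rng, list(cfg.intents)))
    sub = _sample_compatible(schema, intent, rng, cfg)
    q = ground_query(sub, intent, kg, rng, schema, operators=cfg.operators)
    form = VerbalizationForm(_pick(rng, list(cfg.forms)))
    canonical = verbalize(q, form, cfg.templates)
    paraphrases = collect_paraphrases(
        canonical,
        _entities(q),
        cfg.paraphrase_provider,
        cfg.n_paraphrases,
        form,
    )
    pool = [canonical, *paraphrases]
    question = str(_pick(rng, pool))
    return QAExample(
        question=question,
        encoded_query=encode(q.sparql),
        canonical_question=canonical,
        paraphrases=tuple(paraphrases),
        split=split,
        metadata={
            "intent": q.intent.value,
            "n_relations": q.n_relations,
            "functions": sorted({f.op for f in q.filters}),
            "form": form.value,
        },
    )


def assemble_dataset(
    schema: OntologySchema,
    kg: KGStore,
    sizes: Mapping[str, int],
    config: GeneratorConfig | None = None,
    rng: random.Random | None = None,
) -> tuple[list[QAExample], DatasetStats]:
    """Generate train/dev/test splits, disjoint by question text."""
    cfg = config or GeneratorConfig()
    rng = rng or random.Random(0)
    for split, n in sizes.items():
        if n < 0:
            raise ValueError(f"negative size for split {split!r}")
    examples: list[QAExample] = []
    seen: set[str] = set()
    for split in ("train", "dev", "test"):
        n = int(sizes.get(split, 0))
        produced = 0
        attempts = 0
        while produced < n:
            attempts += 1
            if attempts > 200 * max(n, 1):
                raise GenerationError(
                    f"could not produce {n} distinct questions for {split!r}"
                )
            ex = make_example(schema, kg, rng, cfg, split)
            if ex.question in seen:
                continue
            seen.add(ex.question)
            examples.append(ex)
            produced += 1
    return examples, dataset_statistics(examples)


def dataset_statistics(examples: Sequence[QAExample]) -> DatasetStats:
    """Dataset-level statistics: split size, share of examples by relation
    count, and share of examples containing each comparative operator."""
    n = len(examples)
    by_rel = {1: 0, 2: 0, 3: 0}
    by_fn = {op: 0 for op in OPERATORS}
    for ex in examples:
        k = int(ex.metadata.get("n_relations", 0))
        if k in by_rel:
            by_rel[k] += 1
        for op in ex.metadata.get("functions", ()):
            if op in by_fn:
                by_fn[op] += 1
    pct = lambda c: 100.0 * c / n if n else 0.0
    return DatasetStats(
        size=n,
        pct_by_relation_count={k: pct(v) for k, v in by_rel.items()},
        pct_function={k: pct(v) for k, v in by_fn.items()},
    )


def write_jsonl(path: str | Path, examples: Iterable[QAExample]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ex in examples:
            fh.write(json.dumps(ex.to_dict(), ensure_ascii=False) + "\n")


def read_jsonl(path: str | Path) -> list[QAExample]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(QAExample.from_dict(json.loads(line)))
    return out
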