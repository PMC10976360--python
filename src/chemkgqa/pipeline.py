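"""End-to-end question answering with corrective postprocessing.

A question flows through: SI unit conversion → instruction prompt →
translation backend (any prompted text-to-text model) → decoding of the
seq2seq-safe representation → copy correction (restore imperfectly copied
entity literals from the question via Levenshtein-closest substrings) →
relation correction (realign out-of-schema predicates by embedding cosine
similarity) → triple-pattern expansion (names, units, reference states for
human-readable answers) → execution against the knowledge graph.

Translation itself is pluggable: a gold lookup backend, a rule-based
template backend, or an adapter around an external fine-tuned seq2seq
model (full precision or 8-bit — a flag forwarded to the adapter, not
implemented here).  Fine-tuning hyperparameters are housed in
:class:`TrainingConfig` purely for passthrough to an external trainer.
"""

from __future__ import annotations

import re
import time
import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Mapping, Protocol, Sequence

import numpy as np

from . import codec
from .generator import (
    build_species_grounding,
    format_number,
)
from .kg import (
    CORE_PREDICATES,
    DEFAULT_PROLOGUE,
    KGStore,
    OntologySchema,
    decamel,
    execute_select,
)
from .units import DEFAULT_LEXICON, PreprocessedQuestion, UnitEntry, convert_units

__all__ = [
    "PROMPT",
    "prepend_prompt",
    "levenshtein",
    "closest_substring",
    "copy_correct",
    "TrigramEmbedder",
    "relation_correct",
    "ExpansionRules",
    "expand_triples",
    "ExpandError",
    "BackendError",
    "TranslationBackend",
    "GoldBackend",
    "CallableBackend",
    "RuleBasedBackend",
    "TrainingConfig",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
]

#: Instruction prompt prepended to every preprocessed question.
PROMPT = "translate to SPARQL: "


def prepend_prompt(text: str, prompt: str = PROMPT) -> str:
    """Single application of the instruction prompt (caller contract:
    never applied twice)."""
    return prompt + text


# ---------------------------------------------------------------------------
# Copy correction


def levenshtein(a: str, b: str) -> int:
    """Minimum number of single-character insertions, deletions and
    substitutions transforming ``a`` into ``b``."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]


def _sellers(text: str, pattern: str) -> list[int]:
    """Approximate-matching DP: entry ``j`` is the minimum edit distance
    between ``pattern`` and any substring of ``text`` ending at ``j``
    (free start)."""
    n = len(text)
    prev = [0] * (n + 1)
    for i, pc in enumerate(pattern, 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (pc != text[j - 1]),
            )
        prev = cur
    return prev


def closest_substring(text: str, pattern: str) -> tuple[int, int, int]:
    """Substring of ``text`` minimizing Levenshtein distance to ``pattern``.

    Returns ``(start, end, distance)``.  Ties are broken by the smallest
    start index, then the shortest substring — matching an exhaustive scan
    over all substrings.
    """
    n = len(text)
    end_row = _sellers(text, pattern)
    d_min = min(end_row)
    start_row = _sellers(text[::-1], pattern[::-1])
    # entry j' of start_row covers substrings starting at n - j'
    best_start = n
    for jp in range(n, -1, -1):
        if start_row[jp] == d_min:
            best_start = n - jp
            break
    # smallest end >= start achieving d_min, via a fixed-start DP
    m = len(pattern)
    prev = list(range(m + 1))  # lev(text[start:start], pattern[:i])
    if prev[m] == d_min:
        return (best_start, best_start, d_min)
    for j in range(best_start + 1, n + 1):
        cj = text[j - 1]
        cur = [j - best_start] + [0] * m
        for i in range(1, m + 1):
            cur[i] = min(
                prev[i] + 1,
                cur[i - 1] + 1,
                prev[i - 1] + (pattern[i - 1] != cj),
            )
        prev = cur
        if prev[m] == d_min:
            return (best_start, j, d_min)
    raise AssertionError("minimum not reachable from earliest start")


def _literal_spans(query: str) -> Iterator[tuple[int, int, str]]:
    """Spans ``(start, end, raw_content)`` of quoted literals, where the
    span excludes the quotes; backslash escapes are honored."""
    i, n = 0, len(query)
    while i < n:
        c = query[i]
        if c in "\"'":
            j = i + 1
            while j < n:
                if query[j] == "\\":
                    j += 2
                    continue
                if query[j] == c:
                    break
                j += 1
            yield (i + 1, min(j, n), query[i + 1 : min(j, n)])
            i = j + 1
        else:
            i += 1


def _unescape(raw: str) -> str:
    return raw.replace('\\"', '"').replace("\\\\", "\\")


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def copy_correct(
    query: str,
    question: str,
    max_normalized_distance: float | None = None,
) -> str:
    """Replace each grounding literal with the question substring closest
    to it under Levenshtein distance.

    Exact substrings (distance 0) are left unchanged; the model is assumed
    to detect the correct span but copy it imperfectly.  When
    ``max_normalized_distance`` is set, replacements whose distance exceeds
    that fraction of the literal length are skipped.
    """
    if not question:
        raise ValueError("empty question")
    out: list[str] = []
    pos = 0
    for start, end, raw in _literal_spans(query):
        lit = _unescape(raw)
        s, e, dist = closest_substring(question, lit)
        best = question[s:e]
        if max_normalized_distance is not None and lit:
            if dist / max(len(lit), 1) > max_normalized_distance:
                best = lit
        out.append(query[pos:start])
        out.append(_escape(best))
        pos = end
    out.append(query[pos:])
    return "".join(out)


# ---------------------------------------------------------------------------
# Relation correction


class TrigramEmbedder:
    """L2-normalized character-trigram frequency vectors.

    A deterministic, dependency-free embedder for relation surface forms:
    trigrams of the padded text are hashed (CRC32) into a fixed-length
    vector.  A pretrained sentence-embedding model can be plugged in
    through the same ``text -> vector`` interface.
    """

    def __init__(self, dim: int = 1024) -> None:
        self.dim = dim

    def __call__(self, text: str) -> np.ndarray:
        v = np.zeros(self.dim, dtype=np.float64)
        padded = f" {text.lower()} "
        for i in range(len(padded) - 2):
            tri = padded[i : i + 3]
            v[zlib.crc32(tri.encode("utf-8")) % self.dim] += 1.0
        norm = float(np.linalg.norm(v))
        if norm > 0:
            v /= norm
        return v


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = float(np.linalg.norm(u)), float(np.linalg.norm(v))
    if nu == 0 or nv == 0:
        raise ValueError("zero-vector embedding (embedder fault)")
    return float(np.dot(u, v) / (nu * nv))


_OS_TOKEN = re.compile(r"os:([A-Za-z_][A-Za-z0-9_]*)")


def relation_correct(
    query: str,
    schema: OntologySchema,
    embedder: Callable[[str], np.ndarray] | None = None,
) -> str:
    """Realign out-of-schema predicates to their nearest schema relation.

    Each predicate in the ontology namespace that is not a schema relation
    (and not a structural value/unit/reference-state predicate) is replaced
    by the relation whose embedded label is most cosine-similar to the
    embedded, de-camel-cased predicate local name.  Ties break by relation
    IRI order; in-schema predicates are never touched.
    """
    if not schema.relations:
        raise ValueError("empty schema")
    embed = embedder or TrigramEmbedder()
    known = set(schema.relation_local_names) | set(CORE_PREDICATES)
    relations = sorted(schema.relations, key=lambda r: r.iri)
    label_vecs: list[np.ndarray] | None = None

    literal_mask = _literal_positions(query)

    def _realign(local: str) -> str:
        nonlocal label_vecs
        if label_vecs is None:
            label_vecs = [embed(r.label) for r in relations]
        qv = embed(decamel(local))
        best_idx, best_sim = 0, -2.0
        for idx, lv in enumerate(label_vecs):
            sim = cosine_similarity(qv, lv)
            if sim > best_sim:  # strict: first (IRI-ordered) wins ties
                best_idx, best_sim = idx, sim
        return relations[best_idx].local_name

    out: list[str] = []
    pos = 0
    for m in _OS_TOKEN.finditer(query):
        if literal_mask[m.start()]:
            continue
        local = m.group(1)
        if local in known:
            continue
        out.append(query[pos : m.start()])
        out.append(f"os:{_realign(local)}")
        pos = m.end()
    out.append(query[pos:])
    return "".join(out)


def _literal_positions(query: str) -> list[bool]:
    mask = [False] * (len(query) + 1)
    for start, end, _ in _literal_spans(query):
        for k in range(start, end):
            mask[k] = True
    return mask


# ---------------------------------------------------------------------------
# Triple-pattern expansion


class ExpandError(ValueError):
    """The query cannot be structurally parsed for expansion."""


@dataclass(frozen=True)
class ExpansionRules:
    """Configuration of the expansion step: which predicates retrieve
    values/units/reference states and which relations are numeric."""

    relation_qnames: frozenset[str]
    numeric_qnames: frozenset[str]
    iupac_qname: str = "os:hasIUPACName"
    value_qname: str = "os:value"
    unit_qname: str = "os:unit"
    refstate_qname: str = "os:hasReferenceState"
    label_qname: str = "rdfs:label"

    @classmethod
    def from_schema(cls, schema: OntologySchema) -> "ExpansionRules":
        return cls(
            relation_qnames=frozenset(r.qname for r in schema.relations),
            numeric_qnames=frozenset(
                r.qname for r in schema.relations if r.numeric
            ),
        )


@dataclass
class _BodyItem:
    kind: str  # triple | values | filter | optional | other
    raw: str
    terms: tuple[str, ...] = ()


def _tokenize_terms(segment: str) -> list[str]:
    """Split a triple pattern into terms, keeping quoted literals intact."""
    terms: list[str] = []
    i, n = 0, len(segment)
    while i < n:
        c = segment[i]
        if c.isspace():
            i += 1
            continue
        if c in "\"'":
            j = i + 1
            while j < n:
                if segment[j] == "\\":
                    j += 2
                    continue
                if segment[j] == c:
                    break
                j += 1
            terms.append(segment[i : j + 1])
            i = j + 1
            continue
        j = i
        while j < n and not segment[j].isspace():
            j += 1
        terms.append(segment[i:j])
        i = j
    return terms


def _parse_query(query: str) -> tuple[list[str], list[_BodyItem]]:
    m = re.match(
        r"\s*SELECT\s+(?P<sel>.*?)\s*WHERE\s*\{(?P<body>.*)\}\s*$",
        query,
        re.S | re.I,
    )
    if not m:
        raise ExpandError("query is not a parseable SELECT ... WHERE { ... }")
    select_vars = m.group("sel").split()
    body = m.group("body")
    items: list[_BodyItem] = []
    i, n = 0, len(body)
    while i < n:
        if body[i].isspace():
            i += 1
            continue
        rest = body[i:]
        if rest.upper().startswith("VALUES"):
            j = _match_brace(body, body.index("{", i))
            items.append(_BodyItem("values", body[i : j + 1].strip()))
            i = j + 1
        elif rest.upper().startswith("OPTIONAL"):
            j = _match_brace(body, body.index("{", i))
            items.append(_BodyItem("optional", body[i : j + 1].strip()))
            i = j + 1
        elif rest.upper().startswith("FILTER"):
            j = _match_paren(body, body.index("(", i))
            items.append(_BodyItem("filter", body[i : j + 1].strip()))
            i = j + 1
        else:
            j = _find_dot(body, i)
            seg = body[i:j].strip()
            terms = _tokenize_terms(seg)
            if len(terms) != 3:
                raise ExpandError(f"cannot parse triple pattern {seg!r}")
            items.append(_BodyItem("triple", seg + " .", tuple(terms)))
            i = j + 1
    return select_vars, items


def _match_brace(text: str, open_pos: int) -> int:
    depth = 0
    for k in range(open_pos, len(text)):
        if text[k] == "{":
            depth += 1
        elif text[k] == "}":
            depth -= 1
            if depth == 0:
                return k
    raise ExpandError("unbalanced braces")


def _match_paren(text: str, open_pos: int) -> int:
    depth = 0
    for k in range(open_pos, len(text)):
        if text[k] == "(":
            depth += 1
        elif text[k] == ")":
            depth -= 1
            if depth == 0:
                return k
    raise ExpandError("unbalanced parentheses")


def _find_dot(body: str, start: int) -> int:
    """Index of the ``.`` terminating a triple pattern (quote-aware)."""
    i, n = start, len(body)
    quote = None
    while i < n:
        c = body[i]
        if quote is not None:
            if c == "\\":
                i += 2
                continue
            if c == quote:
                quote = None
        elif c in "\"'":
            quote = c
        elif c == ".":
            return i
        elif c == "\n" and body[start:i].strip():
            # tolerate model output lacking the dot separator
            return i
        i += 1
    return n


def expand_triples(query: str, rules: ExpansionRules) -> str:
    """Augment a minimal query with answer-enriching triple patterns.

    Adds IUPAC-name retrieval for the species variable and, for every
    numeric property, unit patterns plus an OPTIONAL reference-state block
    (value, unit, label).  New variables enter the SELECT clause right
    after the variable they qualify.  FILTER clauses are preserved and the
    operation is idempotent (existing blocks are detected and skipped).
    """
    select_vars, items = _parse_query(query)

    species_var = None
    for it in items:
        if it.kind == "triple" and it.terms[1] in rules.relation_qnames:
            species_var = it.terms[0]
            break
    if species_var is None:
        for it in items:
            if it.kind == "triple" and "?SpeciesIRI" in it.terms:
                species_var = "?SpeciesIRI"
                break
    if species_var is None:
        raise ExpandError("species variable not identifiable")

    used_vars = set(re.findall(r"\?[A-Za-z_][A-Za-z0-9_]*", query))

    def fresh(base: str, prefix: str) -> str:
        name = f"?{base}"
        if name not in used_vars:
            return name
        return f"?{prefix}{base}"

    new_items: list[_BodyItem] = []
    has_iupac = any(
        it.kind == "triple" and it.terms[1] == rules.iupac_qname for it in items
    )
    if not has_iupac:
        iupac_value = fresh("IUPACNameValue", "Species")
        iupac_iri = fresh("IUPACNameIRI", "Species")
        new_items.append(
            _BodyItem(
                "triple",
                f"{species_var} {rules.iupac_qname} {iupac_iri} .",
                (species_var, rules.iupac_qname, iupac_iri),
            )
        )
        new_items.append(
            _BodyItem(
                "triple",
                f"{iupac_iri} {rules.value_qname} {iupac_value} .",
                (iupac_iri, rules.value_qname, iupac_value),
            )
        )
        used_vars.update({iupac_value, iupac_iri})
        if species_var in select_vars:
            select_vars.insert(select_vars.index(species_var) + 1, iupac_value)
        else:
            select_vars.insert(0, iupac_value)

    result = new_items + list(items)

    # map property-node variable -> its value variable
    value_of = {
        it.terms[0]: it.terms[2]
        for it in items
        if it.kind == "triple" and it.terms[1] == rules.value_qname
    }
    has_unit = {
        it.terms[0]
        for it in items
        if it.kind == "triple" and it.terms[1] == rules.unit_qname
    }

    for it in list(items):
        if it.kind != "triple" or it.terms[1] not in rules.numeric_qnames:
            continue
        prop_var = it.terms[2]
        if prop_var in has_unit or prop_var not in value_of:
            continue
        value_var = value_of[prop_var]
        base = value_var.lstrip("?")
        base = base[: -len("Value")] if base.endswith("Value") else base
        unit_iri = fresh("UnitIRI", base)
        unit_value = fresh("UnitValue", base)
        rs_iri = fresh("RefStateIRI", base)
        rs_value = fresh("RefStateValue", base)
        rs_unit_iri = fresh("RefStateUnitIRI", base)
        rs_unit_value = fresh("RefStateUnitValue", base)
        used_vars.update(
            {unit_iri, unit_value, rs_iri, rs_value, rs_unit_iri, rs_unit_value}
        )
        block = [
            _BodyItem(
                "triple",
                f"{prop_var} {rules.unit_qname} {unit_iri} .",
                (prop_var, rules.unit_qname, unit_iri),
            ),
            _BodyItem(
                "triple",
                f"{unit_iri} {rules.label_qname} {unit_value} .",
                (unit_iri, rules.label_qname, unit_value),
            ),
            _BodyItem(
                "optional",
                "OPTIONAL {\n"
                f"{prop_var} {rules.refstate_qname} {rs_iri} .\n"
                f"{rs_iri} {rules.value_qname} {rs_value} .\n"
                f"{rs_iri} {rules.unit_qname} {rs_unit_iri} .\n"
                f"{rs_unit_iri} {rules.label_qname} {rs_unit_value} .\n"
                "}",
            ),
        ]
        # insert right after the property's value pattern
        anchor = next(
            k
            for k, x in enumerate(result)
            if x.kind == "triple"
            and x.terms[0] == prop_var
            and x.terms[1] == rules.value_qname
        )
        result[anchor + 1 : anchor + 1] = block
        if value_var in select_vars:
            at = select_vars.index(value_var) + 1
        else:
            at = len(select_vars)
        select_vars[at:at] = [unit_value, rs_value, rs_unit_value]

    lines = [f"SELECT {' '.join(select_vars)}", "WHERE {"]
    for it in result:
        lines.extend(it.raw.split("\n"))
    lines.append("}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Translation backends


class BackendError(RuntimeError):
    """The translation backend could not produce a prediction."""


class TranslationBackend(Protocol):
    """Stateless contract: prompted question text in, encoded query out."""

    name: str

    def translate(self, prompted: str) -> str: ...


@dataclass
class GoldBackend:
    """Lookup backend over generated (question -> encoded query) pairs;
    the reference translator for tests and upper-bound evaluation."""

    mapping: Mapping[str, str]
    prompt: str = PROMPT
    name: str = "gold"

    def translate(self, prompted: str) -> str:
        question = prompted.removeprefix(self.prompt)
        try:
            return self.mapping[question]
        except KeyError:
            raise BackendError(f"question not in gold map: {question!r}")


@dataclass
class CallableBackend:
    """Adapter around any prompted text-to-text callable (e.g. a seq2seq
    model pipeline).  ``eight_bit`` is a precision flag forwarded to the
    wrapped model loader by the caller; it does not change behaviour here."""

    fn: Callable[[str], str]
    name: str = "model"
    eight_bit: bool = False

    def translate(self, prompted: str) -> str:
        return self.fn(prompted)


class RuleBasedBackend:
    """Template-inverse backend: parses questions that follow the canonical
    verbalization templates and reconstructs the encoded query.  Useful as
    a dependency-free stand-in where no trained model is configured."""

    name = "rules"

    _LOOKUP = re.compile(
        r"^(?:what (?:is|are) the|tell me about the|show me the) "
        r"(?P<props>.+?) of (?P<species>.+?)[?.]?$"
    )
    _CLASS = re.compile(
        r"^(?:what (?:is|are) the|tell me about the|show me the) "
        r"(?P<props>.+?) of chemical species classified as (?P<cls>.+?)[?.]?$"
    )
    _KEYWORD = re.compile(r"^(?P<props>.+?) of (?P<species>.+)$")

    def __init__(self, schema: OntologySchema, prompt: str = PROMPT) -> None:
        self.schema = schema
        self.prompt = prompt
        self._by_surface = {}
        for rel in schema.relations:
            for s in rel.surface_forms:
                self._by_surface.setdefault(s.lower(), rel)

    def translate(self, prompted: str) -> str:
        question = prompted.removeprefix(self.prompt).strip()
        m = self._CLASS.match(question)
        if m:
            return self._class_query(m.group("props"), m.group("cls"))
        m = self._LOOKUP.match(question) or self._KEYWORD.match(question)
        if m:
            return self._lookup_query(m.group("props"), m.group("species"))
        raise BackendError(f"question does not match any template: {question!r}")

    def _relations(self, props: str):
        rels = []
        for p in props.split(" and "):
            rel = self._by_surface.get(p.strip().lower())
            if rel is None:
                raise BackendError(f"unknown property surface form {p!r}")
            rels.append(rel)
        return rels

    def _lookup_query(self, props: str, species: str) -> str:
        body = [build_species_grounding(species)]
        select = []
        for rel in self._relations(props):
            base = rel.local_name.removeprefix("has")
            body.append(f"?SpeciesIRI {rel.qname} ?{base}IRI .")
            body.append(f"?{base}IRI os:value ?{base}Value .")
            select.append(f"?{base}Value")
        sparql = (
            f"SELECT {' '.join(select)}\nWHERE {{\n"
            + "\n".join(line for item in body for line in item.split("\n"))
            + "\n}"
        )
        return codec.encode(sparql)

    def _class_query(self, props: str, cls: str) -> str:
        body = [
            "?SpeciesIRI os:hasChemicalClass ?ChemicalClassIRI .",
            f'?ChemicalClassIRI os:value "{cls}" .',
        ]
        select = ["?SpeciesIRI"]
        for rel in self._relations(props):
            base = rel.local_name.removeprefix("has")
            body.append(f"?SpeciesIRI {rel.qname} ?{base}IRI .")
            body.append(f"?{base}IRI os:value ?{base}Value .")
            select.append(f"?{base}Value")
        sparql = (
            f"SELECT {' '.join(select)}\nWHERE {{\n" + "\n".join(body) + "\n}"
        )
        return codec.encode(sparql)


@dataclass(frozen=True)
class TrainingConfig:
    """Fine-tuning hyperparameters, stored for passthrough to an external
    trainer (full-parameter AdamW fine-tuning; no tuning performed here)."""

    learning_rate: float = 2e-4
    adam_epsilon: float = 1e-6
    batch_size: int = 32
    epochs: int = 3
    prompt: str = PROMPT

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.adam_epsilon) <= 0:
            raise ValueError("optimizer constants must be positive")
        if min(self.batch_size, self.epochs) <= 0:
            raise ValueError("batch size and epochs must be positive")


# ---------------------------------------------------------------------------
# The pipeline


@dataclass
class PipelineConfig:
    lexicon: Mapping[str, UnitEntry] = field(
        default_factory=lambda: dict(DEFAULT_LEXICON)
    )
    prompt: str = PROMPT
    do_copy_correct: bool = True
    do_relation_correct: bool = True
    do_expand: bool = True
    max_normalized_distance: float | None = None
    embedder: Callable[[str], np.ndarray] | None = None
    prologue: str = DEFAULT_PROLOGUE


@dataclass
class PipelineResult:
    """Every stage's artifact, preserved even when a later stage fails."""

    question: str
    preprocessed: PreprocessedQuestion | None = None
    predicted_encoded: str | None = None
    decoded: str | None = None
    copy_corrected: str | None = None
    relation_corrected: str | None = None
    expanded: str | None = None
    result_table: list | None = None
    timings: dict = field(default_factory=dict)
    error: tuple[str, str] | None = None

    def to_dict(self) -> dict:
        d = {
            "question": self.question,
            "preprocessed": self.preprocessed.text if self.preprocessed else None,
            "conversions": [
                (c.original, c.converted, c.dimension)
                for c in (self.preprocessed.conversions if self.preprocessed else ())
            ],
            "predicted_encoded": self.predicted_encoded,
            "decoded": self.decoded,
            "copy_corrected": self.copy_corrected,
            "relation_corrected": self.relation_corrected,
            "expanded": self.expanded,
            "result_table": self.result_table,
            "timings": self.timings,
            "error": list(self.error) if self.error else None,
        }
        return d


def run_pipeline(
    question: str,
    backend: TranslationBackend,
    schema: OntologySchema,
    kg: KGStore,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full preprocess → translate → postprocess → execute chain.

    Per-stage wall-clock timings are recorded; a failing stage stops the
    chain but leaves all upstream artifacts in the result, with the
    offending stage named in ``error``.
    """
    cfg = config or PipelineConfig()
    result = PipelineResult(question=question)

    def _stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            value = fn()
        except Exception as exc:
            result.error = (name, str(exc))
            return None
        finally:
            result.timings[name] = time.perf_counter() - t0
        return value

    pre = _stage("preprocess", lambda: convert_units(question, cfg.lexicon))
    if pre is None:
        return result
    prompted = prepend_prompt(pre.text, cfg.prompt)
    result.preprocessed = replace(pre, text=prompted)

    encoded = _stage("translate", lambda: backend.translate(prompted))
    if encoded is None:
        return result
    result.predicted_encoded = encoded

    decoded = _stage("decode", lambda: codec.decode(encoded))
    if decoded is None:
        return result
    result.decoded = decoded

    current = decoded
    if cfg.do_copy_correct:
        corrected = _stage(
            "copy_correct",
            lambda: copy_correct(current, pre.text, cfg.max_normalized_distance),
        )
        if corrected is None:
            return result
        result.copy_corrected = corrected
        current = corrected

    if cfg.do_relation_correct:
        realigned = _stage(
            "relation_correct",
            lambda: relation_correct(current, schema, cfg.embedder),
        )
        if realigned is None:
            return result
        result.relation_corrected = realigned
        current = realigned

    if cfg.do_expand:
        rules = ExpansionRules.from_schema(schema)
        expanded = _stage("expand", lambda: expand_triples(current, rules))
        if expanded is None:
            return result
        result.expanded = expanded
        current = expanded
    else:
        result.expanded = current

    final = current
    table = _stage("execute", lambda: execute_select(kg, final))
    if table is None:
        return result
    result.result_table = table
    return result
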