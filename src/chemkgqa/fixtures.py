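"""Self-contained synthetic knowledge graph and gold datasets.

Everything here exists so the rest of the package is testable without
downloads or trained models: an OntoSpecies-style ontology plus instance
triples (species with identifier subtypes, reified numeric properties
carrying value/unit/optional reference state, chemical classes and uses),
gold question/query datasets with a lookup translation backend, and
controlled corruptions that exercise each corrective postprocessing step
and error category.

The SMILES-like identifier strings are syntactically plausible (balanced
parentheses, paired ring digits) and deliberately built from repeated
motifs — the long, repetitive spans that make verbatim copying hard for
seq2seq models — but are not guaranteed chemically valid: copy correction
is a string problem.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from pathlib import Path

import rdflib
from rdflib import OWL, RDF, RDFS, XSD
from rdflib.namespace import SKOS

from . import codec
from .generator import (
    GeneratorConfig,
    QAExample,
    assemble_dataset,
)
from .kg import OS, KGStore, OntologySchema, load_schema
from .pipeline import _literal_spans

__all__ = [
    "PropertySpec",
    "FixtureConfig",
    "FixtureKG",
    "CorruptionSpec",
    "CorruptionError",
    "CORRUPTION_MODES",
    "INTENDED_CATEGORY",
    "generate_kg",
    "make_gold_dataset",
    "corrupt",
]


@dataclass(frozen=True)
class PropertySpec:
    """One reified numeric property: value range, unit label, and the
    probability that an instance carries a reference state."""

    name: str
    label: str
    low: float
    high: float
    unit: str
    ref_state_p: float = 0.5
    integer: bool = False

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"degenerate range for {self.name}")


@dataclass(frozen=True)
class FixtureConfig:
    n_species: int = 30
    properties: tuple[PropertySpec, ...] = (
        PropertySpec("BoilingPoint", "boiling point", 200.0, 600.0, "K", 0.6),
        PropertySpec("MeltingPoint", "melting point", 50.0, 400.0, "K", 0.6),
        PropertySpec(
            "MolecularWeight", "molecular weight", 16.0, 900.0, "g/mol", 0.0
        ),
        PropertySpec("Charge", "charge", -2.0, 2.0, "e", 0.0, integer=True),
        PropertySpec(
            "OpticalRotation", "optical rotation", -180.0, 180.0, "deg", 0.5
        ),
    )
    classes: tuple[str, ...] = (
        "alcohol",
        "aromatic compound",
        "alkane",
        "ketone",
        "ester",
        "amine",
    )
    uses: tuple[str, ...] = (
        "solvent",
        "nonpolar solvent",
        "fuel",
        "reagent",
        "preservative",
        "lubricant",
    )
    smiles_motifs: tuple[str, ...] = (
        "CC(C)",
        "C(CC(O))",
        "OC(CO)",
        "C(=O)O",
        "CCO",
        "CN(C)",
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")


@dataclass(frozen=True)
class FixtureKG:
    """Generated ontology + instance documents (sorted N-Triples text)."""

    ontology: str
    instances: str
    config: FixtureConfig

    def schema(self) -> OntologySchema:
        g = rdflib.Graph()
        g.parse(data=self.ontology, format="nt")
        return load_schema(g)

    def store(self) -> KGStore:
        g = rdflib.Graph()
        g.parse(data=self.instances, format="nt")
        return KGStore(g)

    def write(self, outdir: str | Path) -> tuple[Path, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        onto = outdir / "ontology.nt"
        inst = outdir / "instances.nt"
        onto.write_text(self.ontology, encoding="utf-8")
        inst.write_text(self.instances, encoding="utf-8")
        return onto, inst


# ---------------------------------------------------------------------------
# Name and SMILES generators

_NAME_PREFIXES = (
    "meth", "eth", "prop", "but", "pent", "hex", "hept", "oct",
    "benz", "tol", "phen", "cyclo", "iso", "neo", "fluor", "chlor", "brom",
)
_NAME_MIDDLES = ("", "ox", "amin", "hydr", "thi", "carb", "sulf")
_NAME_SUFFIXES = (
    "ane", "ene", "yne", "ol", "al", "one", "oate", "amine", "ether", "acid",
)


def _make_name(rng: random.Random, taken: set[str]) -> str:
    for _ in range(1000):
        name = (
            rng.choice(_NAME_PREFIXES)
            + rng.choice(_NAME_MIDDLES)
            + rng.choice(_NAME_SUFFIXES)
        )
        if rng.random() < 0.3:
            name = f"{rng.randint(1, 4)}-{name}"
        if name not in taken:
            taken.add(name)
            return name
    raise RuntimeError("name space exhausted")


def _make_smiles(
    rng: random.Random, motifs: tuple[str, ...], taken: set[str]
) -> str:
    for _ in range(1000):
        parts = ["C"]
        ring = 1
        for _ in range(rng.randint(4, 9)):
            if rng.random() < 0.25 and ring <= 9:
                parts.append(f"C{ring}CCC(C)C{ring}")
                ring += 1
            else:
                parts.append(rng.choice(motifs) * rng.randint(1, 3))
        smiles = "".join(parts)
        if smiles not in taken:
            taken.add(smiles)
            return smiles
    raise RuntimeError("SMILES space exhausted")


def _slug(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "_", text).strip("_")


# ---------------------------------------------------------------------------
# KG generation


def _ontology_graph(config: FixtureConfig) -> rdflib.Graph:
    g = rdflib.Graph()

    def add_class(local: str, label: str, parent: str | None = None):
        c = OS[local]
        g.add((c, RDF.type, OWL.Class))
        g.add((c, RDFS.label, rdflib.Literal(label)))
        if parent:
            g.add((c, RDFS.subClassOf, OS[parent]))
        return c

    add_class("Species", "chemical species")
    add_class("Identifier", "identifier")
    add_class("IUPACName", "IUPAC name", "Identifier")
    add_class("SMILES", "SMILES", "Identifier")
    add_class("Use", "use")
    add_class("ChemicalClass", "chemical class")
    add_class("Unit", "unit")
    add_class("ReferenceState", "reference state")

    def add_relation(local: str, label: str, rng_cls: str, alts: tuple[str, ...] = ()):
        r = OS[local]
        g.add((r, RDF.type, OWL.ObjectProperty))
        g.add((r, RDFS.label, rdflib.Literal(label)))
        g.add((r, RDFS.domain, OS.Species))
        g.add((r, RDFS.range, OS[rng_cls]))
        for a in alts:
            g.add((r, SKOS.altLabel, rdflib.Literal(a)))

    for prop in config.properties:
        add_class(prop.name, prop.label)
        # numeric marker: the property class's os:value is a decimal
        restr = OS[f"{prop.name}ValueRestriction"]
        g.add((restr, RDF.type, OWL.Restriction))
        g.add((restr, OWL.onProperty, OS.value))
        g.add((restr, OWL.someValuesFrom, XSD.decimal))
        g.add((OS[prop.name], RDFS.subClassOf, restr))
        add_relation(
            f"has{prop.name}", prop.label, prop.name, (f"has {prop.label}",)
        )
    add_relation("hasUse", "uses", "Use", ("applications", "has use"))
    add_relation(
        "hasChemicalClass", "chemical class", "ChemicalClass", ("has chemical class",)
    )
    add_relation("hasIUPACName", "IUPAC name", "IUPACName", ("has IUPAC name",))
    add_relation("hasSMILES", "SMILES", "SMILES", ("has SMILES",))
    return g


def _instance_graph(config: FixtureConfig) -> rdflib.Graph:
    rng = random.Random(config.seed)
    g = rdflib.Graph()
    taken_names: set[str] = set()
    taken_smiles: set[str] = set()

    units: dict[str, rdflib.URIRef] = {}

    def unit_node(label: str) -> rdflib.URIRef:
        if label not in units:
            u = OS[f"Unit_{_slug(label)}"]
            g.add((u, RDF.type, OS.Unit))
            g.add((u, RDFS.label, rdflib.Literal(label)))
            units[label] = u
        return units[label]

    def tag_node(kind: str, value: str) -> rdflib.URIRef:
        node = OS[f"{kind}_{_slug(value)}"]
        g.add((node, RDF.type, OS[kind]))
        g.add((node, OS.value, rdflib.Literal(value)))
        g.add((node, RDFS.label, rdflib.Literal(value)))
        return node

    class_nodes = [tag_node("ChemicalClass", c) for c in config.classes]
    use_nodes = [tag_node("Use", u) for u in config.uses]

    for i in range(config.n_species):
        sp = OS[f"Species_{i:04d}"]
        g.add((sp, RDF.type, OS.Species))

        name = _make_name(rng, taken_names)
        iupac = OS[f"Species_{i:04d}_IUPACName"]
        g.add((iupac, RDF.type, OS.IUPACName))
        g.add((iupac, OS.value, rdflib.Literal(name)))
        g.add((sp, OS.hasIUPACName, iupac))

        smiles = _make_smiles(rng, config.smiles_motifs, taken_smiles)
        smi = OS[f"Species_{i:04d}_SMILES"]
        g.add((smi, RDF.type, OS.SMILES))
        g.add((smi, OS.value, rdflib.Literal(smiles)))
        g.add((sp, OS.hasSMILES, smi))

        for prop in config.properties:
            node = OS[f"Species_{i:04d}_{prop.name}"]
            g.add((node, RDF.type, OS[prop.name]))
            if prop.integer:
                value = str(rng.randint(int(prop.low), int(prop.high)))
            else:
                value = f"{rng.uniform(prop.low, prop.high):.2f}"
            g.add((node, OS.value, rdflib.Literal(value, datatype=XSD.decimal)))
            g.add((node, OS.unit, unit_node(prop.unit)))
            g.add((sp, OS[f"has{prop.name}"], node))
            if rng.random() < prop.ref_state_p:
                rs = OS[f"Species_{i:04d}_{prop.name}_RefState"]
                g.add((rs, RDF.type, OS.ReferenceState))
                pressure = rng.choice(("101325", "100000"))
                g.add((rs, OS.value, rdflib.Literal(pressure, datatype=XSD.decimal)))
                g.add((rs, OS.unit, unit_node("Pa")))
                g.add((node, OS.hasReferenceState, rs))

        for cc in rng.sample(class_nodes, rng.randint(1, 2)):
            g.add((sp, OS.hasChemicalClass, cc))
        for use in rng.sample(use_nodes, rng.randint(1, 2)):
            g.add((sp, OS.hasUse, use))
    return g


def _sorted_nt(g: rdflib.Graph) -> str:
    lines = sorted(
        line for line in g.serialize(format="nt").splitlines() if line.strip()
    )
    return "\n".join(lines) + "\n"


def generate_kg(config: FixtureConfig | None = None) -> FixtureKG:
    """Generate the ontology and instance documents (fully reproducible
    for a fixed seed: output text is byte-identical across runs)."""
    cfg = config or FixtureConfig()
    return FixtureKG(
        ontology=_sorted_nt(_ontology_graph(cfg)),
        instances=_sorted_nt(_instance_graph(cfg)),
        config=cfg,
    )


def make_gold_dataset(
    schema: OntologySchema,
    kg: KGStore,
    n: int,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> tuple[list[QAExample], dict[str, str]]:
    """A gold dataset plus its (question -> encoded query) lookup map,
    ready to drive a gold translation backend."""
    examples, _ = assemble_dataset(
        schema, kg, {"train": n}, config, random.Random(seed)
    )
    gold_map = {ex.question: ex.encoded_query for ex in examples}
    assert len(gold_map) == len(examples)  # questions are unique
    return examples, gold_map


# ---------------------------------------------------------------------------
# Controlled corruptions

CORRUPTION_MODES = (
    "typo_in_literal",
    "relation_synonym",
    "structure_drop",
    "function_flip",
    "brace_break",
)

#: The error category (or correction trigger) each mode is built to hit.
INTENDED_CATEGORY = {
    "typo_in_literal": None,  # copy-correction trigger, not a taxonomy class
    "relation_synonym": "relation",
    "structure_drop": "query_structure",
    "function_flip": "function",
    "brace_break": "syntax",
}

_RELATION_VARIANTS = {
    "hasBoilingPoint": "hasBoilingPt",
    "hasMeltingPoint": "hasMeltingPt",
    "hasMolecularWeight": "hasMolWeight",
    "hasOpticalRotation": "hasOptRotation",
    "hasCharge": "hasElectricCharge",
    "hasUse": "hasUsage",
    "hasChemicalClass": "hasChemClass",
    "hasIUPACName": "hasIupacNm",
    "hasSMILES": "hasSmilesStr",
}

_TYPO_ALPHABET = "abcdefghijklmnopqrstuvwxyzCNOS0123456789"


class CorruptionError(ValueError):
    """The requested corruption mode does not apply to this example."""


@dataclass(frozen=True)
class CorruptionSpec:
    mode: str
    magnitude: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in CORRUPTION_MODES:
            raise ValueError(f"unknown corruption mode {self.mode!r}")
        if self.magnitude < 1:
            raise ValueError("magnitude must be >= 1")


def corrupt(
    example: QAExample, spec: CorruptionSpec, schema: OntologySchema | None = None
) -> str:
    """Return a corrupted *encoded* predicted query for ``example``."""
    rng = random.Random(spec.seed)
    sparql = codec.decode(example.encoded_query)
    if spec.mode == "typo_in_literal":
        out = _typo_in_literal(sparql, spec.magnitude, rng)
    elif spec.mode == "relation_synonym":
        out = _relation_synonym(sparql, rng, schema)
    elif spec.mode == "structure_drop":
        out = _structure_drop(sparql, rng)
    elif spec.mode == "function_flip":
        out = _function_flip(sparql)
    else:  # brace_break
        out = _brace_break(sparql)
    return codec.encode(out)


def _typo_in_literal(sparql: str, magnitude: int, rng: random.Random) -> str:
    spans = [s for s in _literal_spans(sparql) if s[2]]
    if not spans:
        raise CorruptionError("no grounding literal to corrupt")
    start, end, raw = spans[rng.randrange(len(spans))]
    lit = list(raw)
    for _ in range(magnitude):
        op = rng.choice(("sub", "ins", "del")) if len(lit) > 1 else "ins"
        pos = rng.randrange(len(lit)) if lit else 0
        if op == "sub":
            choices = [c for c in _TYPO_ALPHABET if c != lit[pos]]
            lit[pos] = rng.choice(choices)
        elif op == "ins":
            lit.insert(pos, rng.choice(_TYPO_ALPHABET))
        else:
            del lit[pos]
    return sparql[:start] + "".join(lit) + sparql[end:]


def _relation_synonym(
    sparql: str, rng: random.Random, schema: OntologySchema | None
) -> str:
    known = set(schema.relation_local_names) if schema else set(_RELATION_VARIANTS)
    present = [
        local
        for local in sorted(set(re.findall(r"os:([A-Za-z_][A-Za-z0-9_]*)", sparql)))
        if local in known and local in _RELATION_VARIANTS
    ]
    if not present:
        raise CorruptionError("no schema relation present to corrupt")
    local = present[rng.randrange(len(present))]
    variant = _RELATION_VARIANTS[local]
    while schema is not None and variant in schema.relation_local_names:
        variant += "X"
    return sparql.replace(f"os:{local}", f"os:{variant}", 1)


def _structure_drop(sparql: str, rng: random.Random) -> str:
    lines = sparql.split("\n")
    candidates = [
        i
        for i, line in enumerate(lines)
        if line.strip().endswith(".")
        and not line.strip().upper().startswith(("VALUES", "FILTER", "OPTIONAL"))
    ]
    if not candidates:
        raise CorruptionError("no triple pattern to drop")
    del lines[candidates[rng.randrange(len(candidates))]]
    return "\n".join(lines)


_F_HIGHER = re.compile(r"FILTER \((\?\w+) > (\S+?)\)")
_F_LOWER = re.compile(r"FILTER \((\?\w+) < (\S+?)\)")
_F_INSIDE = re.compile(r"FILTER \((\S+) < (\?\w+) && (\?\w+) < (\S+?)\)")
_F_OUTSIDE = re.compile(r"FILTER \((\?\w+) < (\S+) \|\| (\?\w+) > (\S+?)\)")


def _function_flip(sparql: str) -> str:
    m = _F_INSIDE.search(sparql)
    if m:  # inside (or around) -> outside
        lo, var, _, hi = m.groups()
        return sparql.replace(
            m.group(0), f"FILTER ({var} < {lo} || {var} > {hi})", 1
        )
    m = _F_OUTSIDE.search(sparql)
    if m:  # outside -> inside
        var, lo, _, hi = m.groups()
        return sparql.replace(
            m.group(0), f"FILTER ({lo} < {var} && {var} < {hi})", 1
        )
    m = _F_HIGHER.search(sparql)
    if m:
        var, a = m.groups()
        return sparql.replace(m.group(0), f"FILTER ({var} < {a})", 1)
    m = _F_LOWER.search(sparql)
    if m:
        var, a = m.groups()
        return sparql.replace(m.group(0), f"FILTER ({var} > {a})", 1)
    raise CorruptionError("no comparative filter to flip")


def _brace_break(sparql: str) -> str:
    pos = sparql.rfind("}")
    if pos < 0:
        raise CorruptionError("no closing brace to remove")
    return sparql[:pos] + sparql[pos + 1 :]
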