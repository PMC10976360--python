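# Methods

## Problem setting

`chemkgqa` answers natural-language chemistry questions against an RDF
knowledge graph in the OntoSpecies modelling style: chemical species carry
identifiers (IUPAC names, SMILES strings) as subclasses of an `Identifier`
class; numeric properties (boiling point, molecular weight, ...) are
reified as nodes holding a decimal `os:value`, an `os:unit` and an
optional reference state; species are annotated with chemical classes and
uses. Question answering is cast as machine translation: the question is
translated into a SPARQL SELECT query by a pluggable sequence-to-sequence
backend, and the query — after corrective postprocessing — is executed
against the graph. A question about an entity absent from the graph must
yield a valid query and an empty result, never a failure.

## Dataset construction

Training corpora are generated from the ontology rather than collected:

1. **Subgraph sampling.** A schema subgraph roots at the species class and
   carries 1–3 outgoing relation edges, sampled without replacement.
   The out-degree is drawn uniformly from {1, 2, 3}; the range is a fixed
   design constraint of the grammar, and uniformity is our choice since no
   particular distribution is canonical. Identifier-typed relations are
   excluded from sampling by default (a config flag restores them),
   because species grounding already matches identifiers through the
   query's VALUES block; sampling them as content edges would duplicate
   that role.
2. **Grounding.** Three query intents exist: `property_lookup` (one-hop,
   species grounded by surface form), `species_search` (species variable
   is the answer; property/use/class values grounded or constrained), and
   `class_property` (two-hop via a chemical class). Entity linking happens
   inside the query: a `VALUES` binding of the literal plus triple
   patterns matching any identifier whose `os:value` equals it, so queries
   carry surface strings rather than entity IRIs. Groundings are drawn
   from instances actually present in the graph, so every generated query
   has at least one answer.
3. **Comparative filters.** Every numeric qualifier of a species search
   receives exactly one of five operators, drawn uniformly: higher
   (`x > a`), lower (`x < a`), inside (`a < x < b`), outside
   (`x < a || x > b`) and around (`0.9a < x < 1.1a`, defined for `a > 0`
   only). Two-sided bounds are normalized so the smaller user-supplied
   value becomes the lower bound (users state ranges in either order);
   inside/around are realized as `&&`-chained comparisons and outside as
   an `||` of two comparisons. Thresholds are derived from a concrete
   instance's value so the filter is satisfiable; when that value is
   non-positive, the `around` operator is excluded from the draw.
4. **Verbalization.** Deterministic templates per (intent, form, operator)
   produce an interrogative, imperative or keyword canonical question
   ("what is the charge of benzene?" / "tell me about the charge of
   benzene." / "charge of benzene"). Templates are configuration data, so
   wording can evolve without code changes.
5. **Paraphrasing.** Only interrogative and imperative questions are
   paraphrased. Providers are pluggable; the default is a deterministic
   rule-based rewriter over relation- and template-side phrases, and a
   remote LLM provider can implement the same protocol. Every candidate
   must contain all grounded entity strings verbatim — entity mentions are
   never altered because entity linking relies on exact string matching —
   and violating candidates are rejected automatically (replacing the
   original manual check). The final question is sampled uniformly from
   the canonical question plus accepted paraphrases.

Splits are disjoint by question text. Dataset statistics report the share
of examples per relation count and the share containing each operator.

## Query encoding

Natural-language tokenizers treat `< > { }` as out-of-vocabulary and strip
whitespace before `?`, which makes raw SPARQL hostile to seq2seq models.
The codec rewrites the four structural characters to HTML entities
(`&lt; &gt; &lcub; &rcub;`) and the variable marker `?name` to `var_name`.
Variable substitution applies only outside quoted literals (a `?` inside a
literal is content, not syntax); the character substitutions apply
globally, which stays bijective because inputs containing any target
sequence are rejected up front. Decoding is the exact inverse; dangling
entity fragments (`&lcub` without `;`) signal malformed model output and
raise a decode error. Dataset queries omit PREFIX declarations to keep
training strings short; the executor injects a standard prologue
(`os:`, `rdfs:`, `rdf:`, `xsd:`).

## Corrective postprocessing

**Copy correction.** Seq2seq models detect the right entity span but copy
long repetitive strings (SMILES) imperfectly. Each quoted grounding
literal is replaced by the substring of the (SI-converted) question
minimizing Levenshtein distance; distance-0 literals are untouched. Ties
break by smallest start index, then shortest substring — note that for a
pure deletion typo this can legitimately select a shorter fragment of the
entity, since it ties the full restoration at equal distance and start.
The search uses a free-start alignment DP (O(|question|·|literal|)) plus a
reverse pass to locate the earliest optimal start; tests verify
equivalence against an exhaustive scan over all substrings. An optional
maximum normalized distance (disabled by default) can veto implausible
replacements in deployments.

**Relation correction.** Predicates in the ontology namespace that are not
schema relations (and not the structural `os:value` / `os:unit` /
`os:hasReferenceState`) are realigned to the schema relation whose
embedded label is most cosine-similar to the embedded, de-camel-cased
predicate local name ("hasBoilingPt" → "has boiling pt"); ties break by
relation IRI order. The default embedder is an L2-normalized
character-trigram frequency vector (CRC32-hashed into 1024 dimensions):
deterministic and dependency-free. A pretrained sentence embedder can be
plugged in through the same `text -> vector` interface. In-schema
predicates are never realigned, so a prediction that confuses two valid
relations is out of reach of this step by design.

**Triple-pattern expansion.** For human-readable answers, the decoded
query is augmented with an IUPAC-name block for the species variable and,
per numeric property, unit patterns plus an OPTIONAL reference-state block
(value, unit, unit label). New SELECT variables are inserted directly
after the variable they qualify. The step is idempotent (existing blocks
are detected) and preserves FILTER clauses. When several numeric
properties appear, the first keeps the bare `?UnitValue`-style names and
later ones are prefixed by their property base to stay collision-free.

## Preprocessing

Quantities are rewritten to SI before translation, since the graph stores
SI values: all conversions are affine (`si = scale·x + offset`), so they
invert exactly; shared-unit ranges ("between 100 and 120 °C") convert both
numbers. The shipped lexicon covers temperature (°C, °F, K → K) and
pressure (atm, bar, mbar, mmHg, Torr, kPa, MPa → Pa) and is plain
configuration data. Unknown units pass through unchanged — units are
assumed dimensionally valid for the quantity they qualify. The instruction
prompt `"translate to SPARQL: "` is prepended once, by the pipeline.

## Evaluation

Exact-match accuracy scores a pair 1 iff the whitespace-token sequences of
the encoded strings are identical (case-sensitive). The corpus score is
4-gram BLEU with brevity penalty on a 0–100 scale over whitespace-tokenized
encoded strings, with exponential smoothing for zero higher-order counts;
a corpus with zero unigram matches scores exactly 0. Scoring runs on the
encoded representation because that is what the model emits.

Incorrect predictions are classified into four aspects of the logical
form, with syntax taking precedence: **syntax** (decoded prediction fails
SPARQL 1.1 parsing), **query_structure** (predicate-abstracted
triple-pattern multiset or SELECT arity differs), **relation** (structures
align but a predicate differs), **function** (comparator/connective
structure of FILTER clauses differs). The non-syntax categories are not
mutually exclusive and the classifier returns a set; percentages are
reported over all examples. These operational definitions are this
package's own — only the category names are canonical. A literal-only copy
error carries no category: it is copy-correction territory.

Per-stage wall-clock timings are recorded in every pipeline result as an
optional latency harness; they produce no acceptance numbers because they
are hardware-dependent.

## Synthetic fixtures

The fixture generator emulates an OntoSpecies-like graph: by default 30
species, each with an IUPAC-like name (syllable grammar) and a SMILES-like
string built from repeated balanced motifs with paired ring digits; five
numeric properties with units (boiling/melting point in K, molecular
weight in g/mol, integer charge, optical rotation in deg), values drawn
uniformly from fixed ranges and reference states attached with the
configured probability (0.5–0.6 for temperature-like properties, so the
OPTIONAL block is exercised both ways); six chemical classes and six uses.
Output is sorted N-Triples, byte-identical for a fixed seed.

What the fixtures deliberately do not model: chemically valid structures
(copy correction is a string problem), duplicate or conflicting property
values from multi-source aggregation, missing properties, and the scale of
a real species graph (tens of thousands of entities). Passing tests
therefore demonstrate the correctness of the grammar, codec, corrections
and metrics — not robustness to noisy real-world data or the translation
quality of any fine-tuned model, which requires external training
infrastructure and is delegated through `TrainingConfig` (AdamW,
learning rate 2e-4, epsilon 1e-6, batch size 32, 3 epochs — passthrough
values, not used locally).

Controlled corruptions map one-to-one onto the pipeline's corrective steps
and error categories: `typo_in_literal` (copy correction),
`relation_synonym` → relation, `structure_drop` → query_structure,
`function_flip` → function, `brace_break` → syntax.

## Numerical and degenerate-input choices

* Numbers are rendered with up to 12 significant digits, trailing zeros
  trimmed, period decimal separator — identical formatting in queries and
  questions.
* `execute_select` sorts result rows lexicographically; the grammar emits
  no ORDER BY, and a stable order makes repeated queries comparable.
* Empty question, empty species surface, empty evaluation corpus, an
  out-of-range out-degree, `around` with a non-positive threshold, a
  two-sided filter missing a bound: all rejected with explicit errors.
* An unparseable *gold* query raises a distinct `DatasetError` so dataset
  faults are never misattributed to the model.

## Problem sizes used in checks

The shipped verification suite uses the default 30-species graph, gold
datasets of 30–50 examples (1000 for the codec round-trip), 200 randomized
copy-correction cases against the exhaustive oracle, 50 recovery cases for
relation correction and 50 cases per corruption mode for the taxonomy —
sizes chosen to exercise every code path quickly on a single CPU.

## Known limitations

* Single inheritance only; no OWL reasoning.
* One intent per query; grounded-species and numeric-filter constraints do
  not mix in a single generated example.
* The rule-based backend covers the canonical templates only; it is a
  stand-in interface demonstration, not a translation model.
* Relation correction only touches out-of-schema predicates; in-schema
  confusions are left to the (external) model.
* The remote SPARQL endpoint path speaks the SPARQL 1.1 protocol over
  HTTP but is exercised only against in-memory graphs in the test suite.
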