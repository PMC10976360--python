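# chemkgqa

Natural-language question answering over chemistry knowledge graphs by
translating questions into SPARQL.

Chemists want to ask a knowledge graph things like *"list the compounds
with chemical class alcohol and boiling point between 100 and 120 °C"*
without knowing SPARQL or the graph's schema. `chemkgqa` implements the
full machinery around a pluggable sequence-to-sequence translation model
for OntoSpecies-style graphs — graphs whose species nodes carry
identifiers (IUPAC names, SMILES), reified numeric properties with units
and optional reference states, chemical classes and uses:

* **Dataset generation** — question/SPARQL training pairs built from the
  ontology itself: schema subgraphs rooted at the species class
  (out-degree 1–3) are grounded against instances, numeric qualifiers get
  one of five comparative operators (higher `x > a`, lower `x < a`,
  inside `a < x < b`, outside `x < a ∨ x > b`, around
  `0.9a < x < 1.1a`), and each logical form is verbalized in
  interrogative, imperative and keyword form, then paraphrased with
  entity mentions preserved verbatim.
* **SPARQL codec** — a seq2seq-safe query representation: `< > { }`
  become HTML entities and the variable marker `?name` becomes
  `var_name`, with an exact inverse.
* **QA pipeline** — SI unit conversion → instruction prompt →
  translation backend → decode → *copy correction* (restore imperfectly
  copied entity literals via Levenshtein-closest substrings of the
  question) → *relation correction* (realign out-of-schema predicates by
  embedding cosine similarity) → *triple-pattern expansion* (names,
  units, reference states) → execution.
* **Evaluation** — exact-match accuracy, a corpus-level 4-gram BLEU-style
  score (0–100), and a four-way error taxonomy (syntax, query structure,
  relation, function).
* **Synthetic fixtures** — a reproducible OntoSpecies-like graph, gold
  datasets and controlled corruptions, so everything is testable offline.

Backends are interchangeable: a gold lookup backend, a rule-based
template backend, or any prompted text-to-text model wrapped in
`CallableBackend` (fine-tuning hyperparameters ride along in
`TrainingConfig` for external trainers).

## Worked example

Generate a fixture knowledge graph and ask a question with the built-in
rule-based backend:

```sh
chemkgqa make-fixtures --out fixtures/ --seed 0
chemkgqa ask \
  --question "what is the boiling point of chemical species classified as alcohol" \
  --backend rules --ontology fixtures/ontology.nt --kg fixtures/instances.nt
```

This prints the postprocessed query — note the automatically added
IUPAC-name, unit and OPTIONAL reference-state blocks —

```sparql
SELECT ?SpeciesIRI ?IUPACNameValue ?BoilingPointValue ?UnitValue ?RefStateValue ?RefStateUnitValue
WHERE {
?SpeciesIRI os:hasIUPACName ?IUPACNameIRI .
?IUPACNameIRI os:value ?IUPACNameValue .
?SpeciesIRI os:hasChemicalClass ?ChemicalClassIRI .
?ChemicalClassIRI os:value "alcohol" .
?SpeciesIRI os:hasBoilingPoint ?BoilingPointIRI .
?BoilingPointIRI os:value ?BoilingPointValue .
?BoilingPointIRI os:unit ?UnitIRI .
?UnitIRI rdfs:label ?UnitValue .
OPTIONAL {
?BoilingPointIRI os:hasReferenceState ?RefStateIRI .
?RefStateIRI os:value ?RefStateValue .
?RefStateIRI os:unit ?RefStateUnitIRI .
?RefStateUnitIRI rdfs:label ?RefStateUnitValue .
}
}
```

followed by one JSON row per answer, e.g.

```json
{"SpeciesIRI": "https://example.org/kb/ontospecies#Species_0005",
 "IUPACNameValue": "pentthiane", "BoilingPointValue": 252.94,
 "UnitValue": "K", "RefStateValue": 100000.0, "RefStateUnitValue": "Pa"}
```

— each row is one alcohol-classified species with its name, boiling point
value and unit, and (when recorded) the reference pressure the value was
measured at.

The same flow from Python:

```python
from chemkgqa import fixtures, GoldBackend, run_pipeline

fkg = fixtures.generate_kg()
schema, store = fkg.schema(), fkg.store()
examples, gold_map = fixtures.make_gold_dataset(schema, store, 50, seed=1)
result = run_pipeline(examples[0].question, GoldBackend(gold_map), schema, store)
print(result.expanded)       # the executed SPARQL
print(result.result_table)   # rows of variable bindings
```

Other subcommands: `chemkgqa generate-dataset` (train/dev/test JSON Lines
plus statistics) and `chemkgqa evaluate` (accuracy, corpus score and
error breakdown for prediction files).

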