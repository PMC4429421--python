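# Methods

## Scope and data flow

The package turns a CDISC ODM 1.3 study export into RDF data cubes and
enrichment linksets. The pipeline is: `odm_io` (parse/serialise the ODM
subset), `lcdc_model` (URI scheme + deduplicated variable dictionary),
`cube_builder` (main + specialised cubes, slices, inter-cube links),
`standards_linker` (CDISC couplings and domain classification),
`med_mapper` (medication cleaning, terminology matching, report),
`validator` (integrity/topology checks), `query_kit` (the three SPARQL
patterns), `synth_fixtures` (synthetic studies and mini-terminologies with
ground truth).

## ODM subset and coercion

Only the content-bearing ODM elements are modelled: StudyEventDef /
FormDef / ItemGroupDef / ItemDef / CodeList on the metadata side and
SubjectData … ItemData on the data side. Elements are matched on local
name, so both plain ODM and OpenClinica-namespaced exports parse; vendor
extension attributes are ignored with a logged notice. Repeat keys default
to `"1"` so every record has a complete coordinate. Values are coerced
strictly per the ItemDef datatype (`int`, `float`, ISO-8601 dates,
codelist membership); failures downgrade the value to missing and log a
warning rather than aborting, because observational study data is
routinely patchy. Partial or non-ISO dates therefore stay as raw text with
a missing typed value.

## URI scheme

Resources are minted from templates following the Linked Data API item /
list convention (identifier-terminated = one instance):
`{base}/dataset/{theme}`, `{base}/dataset/{theme}/slice/{kind}/{key}`,
`{base}/observation/{subject}.{event}.{variable}.{repeat}`,
`{base}/variable/{name}`, `{base}/universe/{theme}/{sub_theme}`,
`{base}/subject/{key}`. Keys are percent-encoded; minting is injective on
(kind, key-tuple). Main-cube observations and observation groups need
their own identities, so two further kinds are used:
`…/observation/main/{…}` and `…/observation-group/{…}`.

## Variable dictionary

ItemDefs collapse on (case-normalised name, datatype); the surviving
variable records every source ItemDef OID, and takes its label and
universe from the first occurrence in definition order. A name reused with
a different datatype is a hard error naming both OIDs. Universes are built
at form level from a required configuration map `form OID → (theme,
sub-theme)`; no inference from form names is attempted. When a shared
variable is captured on two forms at the same visit, the repeat dimension
is qualified with the sub-theme so the dimension tuple stays unique.

## Cube topology

The DSD is the minimal faithful choice: dimensions *subject, timepoint,
variable, repeat*; one generic measure `lcdc:value` carrying the typed
literal; a unit attribute slot. The timepoint dimension uses scheduled
visit labels ("baseline", "month18", …), not calendar dates. Component
nodes are minted IRIs rather than blank nodes so canonically sorted
N-Triples serialisations are byte-stable.

Main-cube slices reference observation groups (`qb:observationGroup`);
specialised-cube slices reference observations (`qb:observation`). Each
observation group is reachable through three independent paths — a phase
series (visit level), a subject section (participant level) and a
sub-theme slice (item-group level). Cross-section slices are
configuration-driven (default: gender); a subject property that varies
across visits draws a warning and the latest-visit value wins. Empty
slices are never emitted. `lcdc:specialisedSeries` /
`lcdc:specialisedSection` connect corresponding time and subject slices
across cubes without range axioms, and the sub-property axioms
`lcdc:specialisedObservation ⊑ qb:observation` and `lcdc:mainObservation ⊑
qb:observation` are emitted exactly once, in the links graph.

## CDISC coupling and domains

Variable couplings are curated input (a map from variable name to
standard-property IRI), recorded as `rdfs:subPropertyOf` pairs in a VoID-
described linkset; `skos:exactMatch` is reserved for instance-level
terminology links. `expand_standard_property` is a reverse transitive
closure over the pair set. Domain classification is rule-driven
(sub-theme or name-glob → domain); defaults cover CM, VS, LB, DM, QS and
MH, while the trial-design domains (TA/TS/TV/SV) are assignable but ship
no default rule. The CDISC concept fixture is a small set of exemplar
VS/LB/CM/DM property IRIs, standing in for the licensed terminology files.

## Medication mapping

Cleaning applies, in order: a curated override lookup (on the case-folded,
whitespace-collapsed raw name — manual fixes as reproducible data), case
folding, parenthetical removal, dosage/strength token stripping
(`500mg`, `1 tablet`, …) and punctuation/whitespace collapse preserving
`+` and `/` for ingredient splitting. A name cleaned to the empty string
is flagged unmappable.

Matching precedence within each phase is exact label > normalised label
(alphanumerics only) > synonym/alias; ties within a method go to the
lexicographically smallest code. The alias sources are ARTG brands (routed
to AMT TP over the ARTG cross-map) and DrugBank names/synonyms (routed to
AMT MP). Substances match UNII first, AMT MS as fallback, with the
cross-mapped MS code reported alongside a UNII hit; any matched ingredient
counts for a multi-ingredient name and all matched ingredients are
recorded. ATC codes are collected over AMT-MP → DrugBank → ATC; a
substance → ATC hop is taken only where the fixture supplies that map and
such codes are flagged separately. Phases are independent — disabling one
never changes another's output. Edit-distance matching
(`difflib.SequenceMatcher`) exists behind a threshold flag, default off,
since dictionary/alias matching is the reported method. Report
percentages round half-up to two decimals, which reproduces the published
mapping-statistics percentages from their printed counts.

## Query patterns

All three templates are rendered deterministically from flat parameters
and return aggregate counts only. Thresholds are strict inequalities, and
each timepoint is evaluated independently (the clinical "most of the time"
qualifier is not modelled); with repeated readings at one visit, any
qualifying reading counts. The standard-term lookup resolves the
sub-property closure in Python and injects it as a SPARQL `VALUES` block —
semantically the `rdfs:subPropertyOf*` lookup, but tractable for the local
engine, whose property-path evaluation over an unbound subject enumerates
the whole graph. Similarly, the transition query's four observation blocks
are braced groups so solutions join on the subject between blocks; a flat
pattern list would be reordered into a cross-product of the four
observation variables. Queries execute as local joins over co-loaded
graphs (cubes + linkset + linked medications + terminology); no network
endpoint is contacted.

## Synthetic data

The generator emulates a prospective ageing cohort: default 200 subjects ×
4 scheduled visits × ~15 variables across five themes (≈10 000 item
values, building in seconds), with 5 % missingness confined to filler
variables so planted signals stay exact. Planted conditions: 25 % of
subjects hypertensive at baseline (both readings drawn strictly above
140/90; the rest strictly below), 60 % with triglycerides below 1.7 mmol/L
at every visit (the rest at ≥ 1.8), 20 % transitioning from a healthy
classification (memory complainer or non-complainer) to MCI after
baseline. Medication strings are canonical terminology names passed
through a reversible corruption model (case shuffling, dosage suffixes,
parentheticals, double spaces) with the intended resolution phase and
codes recorded per record; the kind mix is 30 % trade-name, 15 %
ARTG-alias, 25 % ingredient, 10 % DrugBank-synonym, 10 % substance-only,
10 % junk. The mini-terminology catalogue (~20 drugs, real ATC codes and
DrugBank-style identifiers, synthetic AMT/ARTG/UNII-style codes) is
curated and constant so cross-map closure holds by construction; the
generator's seed parameter does not affect it.

The manifest is derived during generation, independently of the RDF
pipeline, and `expected_answers` recomputes reference query results and
mapping counts by direct record scans. What passing tests therefore show
is that the pipeline is faithful to its inputs — not that real study
exports are as regular as the synthetic ones: real data has richer repeat
structures, partial dates, free-text noise beyond the corruption model,
and medication names outside any terminology.

## Numerical and determinism choices

`random.Random(seed)` drives all generation; identical configs and seeds
give byte-identical XML. Graph comparisons use sorted N-Triples
(`canonical_nt`), which is sound because no blank nodes are emitted.
Percentage rounding uses `decimal` half-up. The acceptance script sizes
its runs (200×4 for conservation, ten 20-subject studies for oracle
agreement, 120 subjects for medication recovery) as desk-scale choices
that keep a full run in a few minutes.

## Known limitations

* No aggregated/roll-up cubes, OLAP operations, or triple-store loading;
  output is files, any SPARQL store can ingest them.
* ODM audit trails, signatures, annotations and full schema validation are
  out of scope; so is define.xml generation.
* The medication phases map at product/substance granularity; dose-form
  and strength-level AMT concepts are not modelled.
* Federated query execution (SERVICE) is not implemented; the drug-class
  pattern is a local join over co-loaded graphs.
* The CDISC and drug terminology fixtures are small curated stand-ins for
  the licensed/full releases; production use requires ingesting real
  AMT/ARTG/UNII/ATC/DrugBank tables in the documented CSV contract.
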