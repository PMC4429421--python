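# lcdc — Linked Clinical Data Cube

`lcdc` converts CDISC ODM clinical-study exports into a **Linked Clinical
Data Cube**: a set of interlinked RDF data cubes that make longitudinal,
multi-domain study data navigable and queryable from several angles at
once, and that couple the study's own variable names to CDISC standard
terminology and its patient-reported medications to linked drug
terminologies.

It is aimed at clinical-research informaticians who receive ODM XML from a
clinical data management system (OpenClinica dialect tolerated) and want to
publish the data as linked data without hand-writing the RDF.

## The model

A study export `Study–Subject–StudyEvent–Form–ItemGroup–Item` is mapped
onto the W3C RDF Data Cube (`qb:`) and DDI-RDF Discovery (`disco:`)
vocabularies:

* the clinical-data section becomes one **main cube** (`qb:DataSet`, also a
  `disco:LogicalDataset`) plus one **specialised cube per theme**
  (Clinical, Cognitive, Imaging, Lifestyle, Study), each declared a
  `void:subset` of the main dataset;
* every non-missing item value becomes a `qb:Observation` with dimensions
  *(subject, timepoint, variable, repeat)* and a single generic measure;
  missing values yield **no** observation, so cube integrity holds on
  patchy observational data;
* an **observation group** per record joins the main-cube observation to
  its specialised-cube counterpart via `lcdc:mainObservation` and
  `lcdc:specialisedObservation` (the latter a sub-property of
  `qb:observation`);
* three slice families give three direct paths to every record:
  **time-series** slices (per timepoint, with a *phase series* per visit),
  **cross-section** slices (per subject property such as gender, plus a
  *subject section* per participant), and **theme** slices (per
  sub-domain universe);
* ItemDefs deduplicate into a DDI-style variable dictionary
  (`disco:Variable` grouped by `disco:Universe`), and a
  `rdfs:subPropertyOf` **linkset** couples study variables to CDISC
  CDASH/SDTM concepts so a query phrased in standard terms (e.g. the VS
  systolic/diastolic blood-pressure properties) resolves the study's own
  names;
* free-text medication names are cleaned by a reproducible rule chain and
  mapped in four phases — AMT **Trade Product** (with ARTG brand aliases),
  AMT **Medicinal Product** (boosted by DrugBank synonyms), **Substance**
  (UNII, falling back to AMT Medicinal Substance, multi-ingredient names
  split on `+`/`/`), and **ATC DDD** codes over the terminology cross-maps
  — emitting `skos:exactMatch` links and a mapping-statistics report.

Three parameterised SPARQL patterns ship with the package: a two-variable
threshold count (e.g. hypertension, both readings strictly above 140/90 at
a visit), a drug-class count (distinct participants per product in a
DrugBank category), and a classification-transition count with a
quantitative bound at both timepoints (e.g. healthy → MCI with
triglycerides < 1.7 mmol/L). All three return aggregate counts only.

Because real study exports are private, the package includes a first-class
synthetic-study generator (`lcdc.synth_fixtures`) that emulates an ageing
cohort at desk scale and records a ground-truth manifest — planted
hypertensive fractions, classification transitions, triglyceride levels
and medication-name corruptions — against which every pipeline stage is
tested.

## Worked example

```sh
lcdc synth --seed 3 --out fx/          # study.xml, manifest.json, termdir/
lcdc build --odm fx/study.xml --out cubes/
lcdc query --pattern threshold --odm fx/study.xml \
    --params p1.yaml --couplings couplings.yaml --out q1.tsv
```

with `p1.yaml` asking for both blood-pressure readings strictly above
140/90 at baseline, phrased in CDISC VS terms, the run prints:

```
count
50
```

— 50 of the 200 synthetic participants are hypertensive at baseline
(exactly the generator's planted 25 % fraction). The drug-class pattern
against the anti-diabetic DrugBank category prints per-product participant
counts:

```
count   name
4       Gliclazide
7       Glimepiride
...
18      Metformin
```

and the transition pattern (healthy → mild cognitive impairment with
normal triglycerides at both visits) prints the grouped counts:

```
count   from    to
11      HC-MC   MCI
10      HC-NMC  MCI
```

The same library calls are available in Python (`lcdc.build_all`,
`lcdc.threshold_count`, `lcdc.map_medications`, ...); the mapping report for
the example's 320 medication records looks like:

```
                                   Mapped  Count Percentage
                                    Total    320    100.00%
Medicinal product/trade product/substance    291     90.94%
                            Trade product    129     40.31%
                        Medicinal product    126     39.38%
                                Substance    131     40.94%
```

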