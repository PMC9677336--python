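# c2m2-toolkit

A self-contained, offline implementation of the **Crosscut Metadata Model
(C2M2)** — the relational metadata schema used to harmonize dataset
descriptions from independent biomedical Data Coordination Centers (DCCs)
into one searchable catalog — together with the full toolchain around it:
schema emission, strict TSV data-package I/O, validation, controlled-
vocabulary term tables, ontology slim maps, a catalog with release
semantics and three search modes, and checksummed submission bundles.

## Who this is for

Data engineers and curators at data coordination centers who need to
express heterogeneous program metadata in a common relational form, and
catalog maintainers who need to validate, merge and search those
submissions. Everything runs offline on plain-text inputs; a synthetic
fixture generator stands in for real program data, and the loaders accept
full-size reference files if you supply them.

## The model

A C2M2 *data package* is a directory of **48 TSV files** (plus a JSON
descriptor in the Frictionless Data Package layout) describing:

- **core entities** — `file` (digital bytestreams), `biosample` (physical
  material), `subject` (organisms), with `project` and `collection` as
  grouping containers and `dcc` as the submitter's contact record;
- **association tables** linking entities to each other
  (`biosample_from_subject`, `file_describes_biosample`, membership in
  collections, …) and to controlled-vocabulary terms
  (`biosample_disease` → Disease Ontology, `biosample.anatomy` → UBERON,
  `file.file_format` → EDAM, substances → PubChem, …);
- **term tables**, one per supported vocabulary, listing exactly the terms
  used anywhere in the submission with names, descriptions and synonyms;
- **admin tables**, notably `id_namespace`.

Every entity record carries a mandatory two-part C2M2 ID — a registered
`id_namespace` prefix plus a DCC-chosen `local_id` — whose concatenation is
unique across the whole catalog, plus an optional persistent ID (DOI,
minid, DRS URI). Only **3 records** are strictly required for a valid
package: a DCC contact record, one attribution project, and one registered
ID namespace; every file, biosample and subject must be linked to exactly
one project.

Submissions are validated (structure → keys → foreign keys → required
records → project links → vocabulary), reviewed, approved, and published by
**full replacement**: each release holds exactly one approved submission
per DCC, and incremental updates are deliberately unsupported. The catalog
answers faceted Boolean search, free-text keyword search over term names /
descriptions / synonyms and container metadata, and term-centric search;
*slim maps* roll specific ontology terms up to their minimal general
ancestors over the `is_a` DAG so broad searches keep full recall.
Connectivity statistics — the percentage of records of one type with at
least one link to another — summarize how findable a submission is.

## Worked example

Generate a synthetic submission with matching mini-ontologies, validate,
bundle, submit, approve, release, and query it:

```sh
$ c2m2 fixtures package --seed 11 --out pkg --refs refs
wrote package (seed 11) to pkg
$ c2m2 validate pkg --refs refs
valid
$ c2m2 bundle pkg --dcc EXAMPLE --out sub.zip
wrote sub.zip
$ c2m2 submit sub.zip --catalog catalog.db --refs refs
submission EXAMPLE:1: in-review
$ c2m2 approve --catalog catalog.db --submission EXAMPLE:1
submission EXAMPLE:1: approved
$ c2m2 release --catalog catalog.db
EXAMPLE: submission EXAMPLE:1
```

`c2m2 stats` then reports, among others:

```
files: 20
biosample->substance: {'percent': 30.0, 'empty': False}
file->data_type:      {'percent': 80.0, 'empty': False}
```

meaning 30% of biosamples carry at least one chemical-substance link and
80% of files are annotated with a data type — so a portal user faceting on
data type can reach 80% of this submission's files. Faceted search:

```
$ c2m2 query --catalog catalog.db --entity file --facet file_format=EDAM:0000003
dcc      id_namespace                    local_id  ...  file_format
EXAMPLE  https://ns.example.org/example  FIL0007   ...  EDAM:0000003
...
# 10 records
```

The same operations are available as a library (`c2m2.validate_package`,
`c2m2.query_faceted`, `c2m2.summary_stats`, …).

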