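# Methods

This note records the modelling and numerical choices behind the toolkit,
what the synthetic fixtures do and do not emulate, and the known limits of
both.

## The table inventory

The model fixes the six core tables (`file`, `biosample`, `subject`,
`project`, `collection`, `dcc`), the `id_namespace` admin table, the
fourteen controlled-vocabulary association tables and seven entity CV
fields, and a total of 48 tables — but no public enumeration of the full
partition exists at that version. The shipped inventory is therefore a
documented reconstruction frozen under version tag `2022.04`: the
constrained tables above, plus two admin enumerations
(`subject_granularity`, `subject_role`), ten container/provenance
associations (`project_in_project`, `collection_in_collection`, the three
`*_in_collection` tables, `collection_defined_by_project`,
`file_describes_biosample`, `file_describes_subject`,
`file_describes_collection`, `biosample_from_subject`), five further
associations modelled on the live schema (`collection_phenotype`,
`protein_gene`, `phenotype_gene`, `phenotype_disease`,
`substance_compound`), and one term table per supported vocabulary (ten).
It conforms to every published structural constraint but makes no claim of
byte-level fidelity to the reference ER diagram.

Term tables carry exactly `id`, `name`, `description`, `synonyms`;
per-term provisional/obsolete status lives in the reference files, not the
submission, so a package never asserts curation state it does not own.

## TSV dialect

UTF-8, LF newlines, no quoting. Values containing literal tabs, carriage
returns or newlines are rejected rather than escaped: no escaping
convention is defined for the format, and refusing ambiguity keeps
serialisation canonical — a given package always produces byte-identical
files, so packages can be compared and bundled by checksum. Empty cells
encode nulls for optional fields; an empty required cell is a
`MISSING_VALUE` error. Record order is preserved as given; headers must
match the schema field order exactly.

## Identifiers

The global key is `namespace | local_id` with `|` as separator; the
separator is forbidden inside namespace tokens, which makes concatenation
injective by construction (property-tested). Namespace "registration" is
modelled as a row in the `id_namespace` table plus catalog-level
uniqueness; there is no network authority. Persistent-ID classification is
purely syntactic (prefix and URI-shape rules, most specific first); no
checksum semantics are assumed for minids or DRS IDs and nothing is ever
dereferenced.

## Vocabulary handling

CURIE detection requires a whole-string `PREFIX:LOCAL` match with a
case-sensitively registered prefix; Ensembl gene IDs and UniProtKB
accessions are matched by dedicated accession patterns since they are not
colon-delimited. Reference files are plain TSVs (`id`, `name`,
`description`, pipe-separated `synonyms`, `obsolete`, `replaced_by`) with a
provisional-term sidecar: trivially diffable, generable by the fixtures
module, and loadable at full ontology scale if a user converts a real
release. Synonyms are stored because keyword search over names,
descriptions *and synonyms* requires them.

Term-table building scans every CV-bound entity field and association
column — never the term tables themselves — which makes the builder
idempotent. Obsolete terms remain usable (datasets that cannot be updated
must keep validating after the vocabulary moves on); provisional terms are
accepted from the sidecar before the curation authority approves them.

## Slim maps

Only `is_a` edges are traversed. `map_to_slim` returns *all minimal* slim
ancestors: where a term has several incomparable slim ancestors the record
appears under each facet, trading precision for recall, which matches the
purpose of slims (broad search without losing results). Terms the slim
does not cover land in a reserved `unclassified` bucket rather than
vanishing. The rollup is checked against a brute-force oracle (repeated
edge relaxation, then pruning of non-minimal ancestors) on random DAGs of
up to 200 nodes.

## Validation

Checks run in a fixed order and accumulate issues under a closed code set
(twelve codes); the code taxonomy and ordering are this package's own,
since testable contracts need machine-readable codes. Decisions worth
recording:

- *orphan vs dangling*: an empty project link on a file/biosample/subject
  is `ORPHAN_ENTITY`; a non-empty link that resolves nowhere is
  `FK_VIOLATION`.
- *collections are exempt* from the one-project rule: they are containers,
  not tangible experimental resources (they attach to projects via
  `collection_defined_by_project` instead).
- entity `id_namespace` columns are checked by a dedicated registration
  rule (`NAMESPACE_UNREGISTERED`), not declared as schema foreign keys, and
  CV-bound columns are checked by the term rules, not FK rules — so each
  planted defect surfaces under exactly one code instead of cascading.
- the term-table comparison (rule 8) runs over terms not already reported
  as unknown or mis-vocabularied, for the same single-code reason.

Lightweight validation (file inventory, headers, rows, keys) is a strict
subset of deep validation; the bundler runs it pre-upload, ingest runs the
full set.

## Catalog

Links for connectivity are direct association rows plus shared collection
membership; the published material shows the statistic but not its
formula, so this definition was chosen to match its stated purpose
(findability coverage: "can a user faceting on B reach this A record?").
Connectivity over an empty entity set is reported as 0% with an explicit
`empty` flag rather than NaN. Keyword search tokenizes on
non-alphanumerics, lowercases, and matches whole tokens only — substring
matching is disabled as the simplest reproducible contract. Keyword scope
for a record: its own term texts, its name/description fields, its
project's and collections' metadata and terms, and terms attached to
directly linked records (e.g. substances administered to a biosample's
source subject). Project hierarchy is *not* traversed for keyword matches
(direct project only); flagged as a possible extension. Release cadence is
an explicit `build_release` call, not a timer. The backing store is a
single sqlite file whose schema mirrors the registry plus `_submission` /
`_dcc` provenance columns.

## Bundles

BagIt layout inside a zip: payload under `data/` (TSVs plus a copy of the
schema descriptor), SHA-256 manifest and tag manifest, provenance
(submitting DCC, toolkit version, bagging timestamp, schema version) in
`bag-info.txt`. Timestamps are injected parameters and zip entry dates are
fixed, so bundles are deterministic and comparable by digest. The exact
field set of the provenance block is this package's reconstruction.

## The synthetic-data generator

The generator emulates the *relational shape* of a submission: entity
inventories with registered namespaces and project attribution, collection
memberships, derivation links, and controlled-vocabulary annotations drawn
from generated mini-ontologies (rooted trees of configurable depth and
branching, widened to the configured vocabulary size, with depth-1 slims,
one obsolete term with a live replacement, and one provisional term per
vocabulary).

Two properties make ground truth exact rather than statistical:

- **exact-count planting** — an annotation rate *r* over *n* records
  plants exactly `round(r·n)` annotations (never Bernoulli draws), so
  connectivity percentages are exact targets;
- **one RNG stream per artifact kind**, each derived from the single seed,
  so identical configs give byte-identical packages and adding new
  artifact kinds later cannot shift existing output.

Default rates (e.g. `file.file_format` 1.0, `file.data_type` 0.8,
`biosample_substance` 0.3) describe a mid-complexity submission: full
format annotation, high but incomplete data-type coverage, partial
clinical/chemical links — the regime in which connectivity dashboards are
informative. Default entity counts (20 files, 10 biosamples, 5 subjects,
3 collections) keep every package small enough for exhaustive brute-force
cross-checks in tests; test and acceptance runs use tens of such packages
(≤ a few hundred records each) rather than portal-scale inventories.

The generator deliberately does **not** emulate: the statistical profile of
real programs (file-count magnitudes, term-frequency distributions),
free-text idiosyncrasy, multi-namespace submissions from one DCC, or
real ontology structure (mini-DAGs are shallow and regular). Passing tests
therefore demonstrate correctness of the mechanics — validation, search,
statistics, round trips — on structurally faithful inputs, not performance
or term-mapping quality on real metadata.

For seeded-defect packages the generator reserves one annotation-free,
membership-free file record and targets row-level defects at it, so each
injected defect triggers exactly its own validation code.

## Known limitations

- No streaming: packages are held in memory (fine at desk scale; a
  multi-gigabyte inventory would need a different I/O layer).
- Queries evaluate in Python over per-package indexes rather than pushing
  into sqlite; correct and adequate at tested scales, not tuned for
  millions of records.
- The `Table 1` panel-B cells and the 48-table partition are labelled
  reconstructions (see above); panel A cells are carried verbatim.
- Only syntactic checks for persistent IDs; no resolution.
- Slims consume only `is_a` edges; other relations (e.g. `part_of`) are
  ignored unless a user encodes them as extra DAG edges.
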