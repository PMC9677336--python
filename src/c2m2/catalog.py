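"""The metadata catalog: ingest, review, releases, search, statistics.

Submissions from each DCC are validated at ingest, reviewed, approved and
published by full replacement: every release holds exactly one approved
submission per DCC, a newly approved submission completely replaces that
DCC's previous public data, and a DCC with no new approval keeps its prior
public submission unchanged.  Partial (incremental) updates are deliberately
unsupported.  All submissions, including rejected ones, are retained.

Three search modes are offered over the merged public view: faceted search
with include/exclude term sets (optionally on slim terms), free-text keyword
search over term names/descriptions/synonyms and container metadata, and
term-centric search returning every associated record grouped by entity
type.  Summary statistics cover per-table row counts and inter-entity
connectivity — the percentage of records of one type with at least one link
to another — which is how submitters gauge the findability of their data.
"""

from __future__ import annotations

import json
import re
import sqlite3
from collections import Counter
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from . import errors, slim as slim_mod, tsv, validate as validate_mod
from .errors import C2M2Error
from .identifiers import make_global_key
from .vocab import VOCABULARIES, term_table_name

ENTITY_TYPES = ("file", "biosample", "subject", "project", "collection")

#: status lifecycle (forward-only); "rejected" is a terminal side state.
STATUSES = ("uploaded", "in-review", "approved", "public", "rejected")

#: facet name -> source, per entity type.  ("field", column) reads an entity
#: CV column; ("assoc", table, column) reads a CV association table.
FACETS = {
    "file": {
        "file_format": ("field", "file_format"),
        "compression_format": ("field", "compression_format"),
        "data_type": ("field", "data_type"),
        "assay_type": ("field", "assay_type"),
        "analysis_type": ("field", "analysis_type"),
    },
    "biosample": {
        "assay_type": ("field", "assay_type"),
        "anatomy": ("field", "anatomy"),
        "disease": ("assoc", "biosample_disease", "disease"),
        "substance": ("assoc", "biosample_substance", "substance"),
        "gene": ("assoc", "biosample_gene", "gene"),
    },
    "subject": {
        "phenotype": ("assoc", "subject_phenotype", "phenotype"),
        "disease": ("assoc", "subject_disease", "disease"),
        "substance": ("assoc", "subject_substance", "substance"),
        "taxonomy": ("assoc", "subject_role_taxonomy", "taxonomy_id"),
    },
    "collection": {
        "anatomy": ("assoc", "collection_anatomy", "anatomy"),
        "disease": ("assoc", "collection_disease", "disease"),
        "gene": ("assoc", "collection_gene", "gene"),
        "substance": ("assoc", "collection_substance", "substance"),
        "compound": ("assoc", "collection_compound", "compound"),
        "taxonomy": ("assoc", "collection_taxonomy", "taxon"),
        "protein": ("assoc", "collection_protein", "protein"),
        "phenotype": ("assoc", "collection_phenotype", "phenotype"),
    },
    "project": {},
}

#: facet -> vocabulary, for slim expansion.
FACET_VOCAB = {
    "file_format": "EDAM", "compression_format": "EDAM", "data_type": "EDAM",
    "assay_type": "OBI", "analysis_type": "OBI", "anatomy": "UBERON",
    "disease": "DiseaseOntology", "substance": "PubChem",
    "compound": "PubChem", "gene": "Ensembl", "phenotype": "HPO",
    "taxonomy": "NCBITaxonomy", "protein": "UniProtKB",
}

_MEMBERSHIP_TABLES = {
    "file": "file_in_collection",
    "biosample": "biosample_in_collection",
    "subject": "subject_in_collection",
}


@dataclass
class Submission:
    dcc: str
    sequence: int
    status: str
    package: object
    received_at: str = "1970-01-01T00:00:00Z"
    report: object = None

    @property
    def id(self):
        return f"{self.dcc}:{self.sequence}"


@dataclass(frozen=True)
class FacetFilter:
    """One facet constraint: include any-of, exclude all-of."""

    facet: str
    include: frozenset = frozenset()
    exclude: frozenset = frozenset()
    slim: bool = False

    def __post_init__(self):
        object.__setattr__(self, "include", frozenset(self.include))
        object.__setattr__(self, "exclude", frozenset(self.exclude))
        if self.include & self.exclude:
            raise C2M2Error(errors.BAD_FACET,
                            f"facet {self.facet!r}: include and exclude "
                            "overlap")


@dataclass
class QueryResult:
    entity_type: str
    records: list                     # (dcc, record-dict) pairs
    facet_counts: dict                # facet -> Counter of raw term values

    def __len__(self):
        return len(self.records)

    def local_ids(self):
        return sorted(r["local_id"] for _, r in self.records
                      if "local_id" in r)

    def to_tsv(self):
        if not self.records:
            return ""
        fields = list(self.records[0][1])
        lines = ["\t".join(["dcc"] + fields)]
        for dcc, record in self.records:
            lines.append("\t".join(
                [dcc] + [(record.get(f) or "") for f in fields]))
        return "\n".join(lines) + "\n"


@dataclass
class ConnectivityStat:
    percent: float
    empty: bool = False


@dataclass
class SummaryStats:
    row_counts: dict
    connectivity: dict                # (from, to) -> ConnectivityStat

    def to_json(self):
        return json.dumps({
            "row_counts": self.row_counts,
            "connectivity": {
                f"{a}->{b}": {"percent": s.percent, "empty": s.empty}
                for (a, b), s in sorted(self.connectivity.items())},
        }, indent=1)


@dataclass
class StatsDelta:
    table_deltas: dict
    connectivity_deltas: dict


# ---------------------------------------------------------------------------
# Per-package index (built once per package, reused by the search modes).
# ---------------------------------------------------------------------------

class PackageIndex:
    """Precomputed lookups over one data package."""

    def __init__(self, pkg):
        self.pkg = pkg
        reg = pkg.registry

        def gk(record, prefix=""):
            return make_global_key(record[f"{prefix}id_namespace"],
                                   record[f"{prefix}local_id"])

        self.records = {}         # entity -> {gk: record}
        for entity in ENTITY_TYPES:
            self.records[entity] = {
                gk(r): r for r in pkg.tables[entity].records
                if r.get("id_namespace") and r.get("local_id")}

        # facet -> {gk: set(term)}
        self.facet_terms = {e: {} for e in ENTITY_TYPES}
        for entity, facets in FACETS.items():
            for facet, source in facets.items():
                values = {}
                if source[0] == "field":
                    for key, record in self.records[entity].items():
                        v = record.get(source[1])
                        if v is not None:
                            values.setdefault(key, set()).add(v)
                else:
                    _, table_name, column = source
                    for row in pkg.tables[table_name].records:
                        ns = row.get(f"{entity}_id_namespace")
                        local = row.get(f"{entity}_local_id")
                        v = row.get(column)
                        if ns and local and v is not None:
                            values.setdefault(
                                make_global_key(ns, local), set()).add(v)
                self.facet_terms[entity][facet] = values

        # entity gk -> set of collection gks (direct membership)
        self.collections_of = {e: {} for e in ("file", "biosample", "subject")}
        for entity, table_name in _MEMBERSHIP_TABLES.items():
            for row in pkg.tables[table_name].records:
                key = make_global_key(row[f"{entity}_id_namespace"],
                                      row[f"{entity}_local_id"])
                ckey = make_global_key(row["collection_id_namespace"],
                                       row["collection_local_id"])
                self.collections_of[entity].setdefault(key, set()).add(ckey)

        # linked records: biosample -> subjects, file -> biosamples/subjects
        self.linked = {e: {} for e in ENTITY_TYPES}
        for row in pkg.tables["biosample_from_subject"].records:
            b = make_global_key(row["biosample_id_namespace"],
                                row["biosample_local_id"])
            s = make_global_key(row["subject_id_namespace"],
                                row["subject_local_id"])
            self.linked["biosample"].setdefault(b, set()).add(("subject", s))
            self.linked["subject"].setdefault(s, set()).add(("biosample", b))
        for table_name, other in (("file_describes_biosample", "biosample"),
                                  ("file_describes_subject", "subject")):
            for row in pkg.tables[table_name].records:
                f = make_global_key(row["file_id_namespace"],
                                    row["file_local_id"])
                o = make_global_key(row[f"{other}_id_namespace"],
                                    row[f"{other}_local_id"])
                self.linked["file"].setdefault(f, set()).add((other, o))
                self.linked[other].setdefault(o, set()).add(("file", f))

        # term id -> (name, description, synonyms) from the term tables
        self.term_text = {}
        for vocabulary in VOCABULARIES:
            for row in pkg.tables[term_table_name(vocabulary)].records:
                self.term_text[row["id"]] = (
                    row.get("name") or "", row.get("description") or "",
                    row.get("synonyms") or "")

    def all_terms(self, entity, key):
        """Every CV term attached directly to one record."""
        out = set()
        for facet_values in self.facet_terms[entity].values():
            out |= facet_values.get(key, set())
        return out


def _tokens(text):
    return {t for t in re.split(r"[^a-z0-9]+", text.lower()) if t}


# ---------------------------------------------------------------------------
# Store and release lifecycle.
# ---------------------------------------------------------------------------

class PublicView:
    """The merged release: at most one public submission per DCC."""

    def __init__(self, submissions):
        self.submissions = dict(submissions)   # dcc -> Submission
        self._indexes = {}

    def index(self, dcc):
        if dcc not in self._indexes:
            self._indexes[dcc] = PackageIndex(self.submissions[dcc].package)
        return self._indexes[dcc]

    def iter_indexes(self):
        for dcc in sorted(self.submissions):
            yield dcc, self.index(dcc)

    def global_keys(self):
        """Every entity global key in the view (collision check surface)."""
        keys = []
        for _, idx in self.iter_indexes():
            for entity in ENTITY_TYPES:
                keys.extend(idx.records[entity])
        return keys


class CatalogStore:
    """All submissions ever received, plus the current public view."""

    def __init__(self, registry):
        self.registry = registry
        self.submissions = []
        self.public_view = PublicView({})

    def for_dcc(self, dcc):
        return [s for s in self.submissions if s.dcc == dcc]

    def get(self, submission_id):
        for s in self.submissions:
            if s.id == submission_id:
                return s
        raise KeyError(submission_id)

    def ingest(self, dcc, package, refs=None, provisional=None,
               received_at="1970-01-01T00:00:00Z"):
        """Deep-validate and register a submission.

        A valid package enters at status ``uploaded``; an invalid one is
        retained at status ``rejected`` with the validation report attached.
        Prior submissions are never touched.
        """
        if isinstance(package, (str, Path)):
            report = validate_mod.validate_package(package, self.registry,
                                                   refs, provisional)
            pkg = tsv.read_package(package, self.registry, issues=[])
        else:
            pkg = package
            report = validate_mod.validate_package(pkg, self.registry, refs,
                                                   provisional)
        sub = Submission(
            dcc=dcc, sequence=len(self.for_dcc(dcc)) + 1,
            status="uploaded" if report.valid else "rejected",
            package=pkg, received_at=received_at, report=report)
        self.submissions.append(sub)
        return sub

    @staticmethod
    def _advance(sub, target):
        order = ("uploaded", "in-review", "approved", "public")
        if sub.status == "rejected" or target not in order or \
                order.index(target) != order.index(sub.status) + 1:
            raise C2M2Error(
                errors.BAD_CONFIG,
                f"cannot move submission {sub.id} from {sub.status!r} to "
                f"{target!r} (transitions are forward-only)")
        sub.status = target

    def review(self, sub):
        self._advance(sub, "in-review")

    def approve(self, sub):
        self._advance(sub, "approved")

    def reject(self, sub):
        if sub.status in ("approved", "public"):
            raise C2M2Error(errors.BAD_CONFIG,
                            f"cannot reject {sub.id} after approval")
        sub.status = "rejected"

    def build_release(self):
        """Publish: newest approved submission per DCC replaces that DCC's
        public data wholesale; DCCs with nothing newly approved keep their
        prior public submission unchanged.  Idempotent."""
        public = dict(self.public_view.submissions)
        for dcc in sorted({s.dcc for s in self.submissions}):
            approved = [s for s in self.for_dcc(dcc) if s.status == "approved"]
            if approved:
                newest = max(approved, key=lambda s: s.sequence)
                newest.status = "public"
                public[dcc] = newest
        self.public_view = PublicView(public)
        return self.public_view

    # -- persistence (single-file embedded relational database) ------------

    def save(self, path):
        """Persist every submission into one sqlite file.

        The relational schema mirrors the registry, with ``_submission`` and
        ``_dcc`` provenance columns on every table.
        """
        path = Path(path)
        if path.exists():
            path.unlink()
        conn = sqlite3.connect(path)
        try:
            conn.execute(
                "CREATE TABLE _submission (n INTEGER PRIMARY KEY, dcc TEXT, "
                "sequence INTEGER, status TEXT, received_at TEXT, "
                "is_public INTEGER, report TEXT)")
            for name in self.registry.list_tables():
                spec = self.registry.tables[name]
                cols = ", ".join(f'"{f}" TEXT' for f in spec.field_names)
                conn.execute(f'CREATE TABLE "{name}" ({cols}, '
                             '_submission INTEGER, _dcc TEXT)')
            for n, sub in enumerate(self.submissions):
                report_json = (sub.report.to_json_lines()
                               if sub.report is not None else None)
                conn.execute(
                    "INSERT INTO _submission VALUES (?, ?, ?, ?, ?, ?, ?)",
                    (n, sub.dcc, sub.sequence, sub.status, sub.received_at,
                     int(self.public_view.submissions.get(sub.dcc) is sub),
                     report_json))
                for name in self.registry.list_tables():
                    spec = self.registry.tables[name]
                    table = sub.package.tables[name]
                    ph = ", ".join("?" * (len(spec.field_names) + 2))
                    conn.executemany(
                        f'INSERT INTO "{name}" VALUES ({ph})',
                        [tuple(r.get(f) for f in spec.field_names)
                         + (n, sub.dcc) for r in table.records])
            conn.commit()
        finally:
            conn.close()
        return path

    @classmethod
    def load(cls, path, registry):
        store = cls(registry)
        conn = sqlite3.connect(path)
        try:
            public = {}
            rows = conn.execute(
                "SELECT n, dcc, sequence, status, received_at, is_public "
                "FROM _submission ORDER BY n").fetchall()
            for n, dcc, sequence, status, received_at, is_public in rows:
                pkg = tsv.DataPackage.empty(registry)
                for name in registry.list_tables():
                    spec = registry.tables[name]
                    cols = ", ".join(f'"{f}"' for f in spec.field_names)
                    for values in conn.execute(
                            f'SELECT {cols} FROM "{name}" '
                            "WHERE _submission = ? ORDER BY rowid", (n,)):
                        pkg.tables[name].records.append(
                            dict(zip(spec.field_names, values)))
                sub = Submission(dcc=dcc, sequence=sequence, status=status,
                                 package=pkg, received_at=received_at)
                store.submissions.append(sub)
                if is_public:
                    public[dcc] = sub
            store.public_view = PublicView(public)
        finally:
            conn.close()
        return store


# ---------------------------------------------------------------------------
# Search modes.
# ---------------------------------------------------------------------------

def _slim_image(terms, facet, dags, slims):
    vocabulary = FACET_VOCAB.get(facet)
    if dags is None or slims is None or vocabulary not in dags:
        raise C2M2Error(errors.BAD_FACET,
                        f"no slim map available for facet {facet!r}")
    image = set()
    for term in terms:
        mapped = (slim_mod.map_to_slim(dags[vocabulary], slims[vocabulary],
                                       term)
                  if term in dags[vocabulary] else ())
        image.update(mapped if mapped else {slim_mod.UNCLASSIFIED})
    return image


def query_faceted(view, entity_type, filters, dags=None, slims=None):
    """Faceted Boolean search: conjunction across filters; within a filter,
    include is a union and exclude removes matches.  Slim filters compare
    against the record's slim image instead of its raw terms."""
    if entity_type not in ENTITY_TYPES:
        raise C2M2Error(errors.BAD_FACET, f"unknown entity {entity_type!r}")
    known = FACETS[entity_type]
    for f in filters:
        if f.facet not in known:
            raise C2M2Error(errors.BAD_FACET,
                            f"{entity_type} has no facet {f.facet!r}")

    survivors = []
    for dcc, idx in view.iter_indexes():
        for key, record in idx.records[entity_type].items():
            ok = True
            for f in filters:
                raw = idx.facet_terms[entity_type][f.facet].get(key, set())
                terms = (_slim_image(raw, f.facet, dags, slims)
                         if f.slim else raw)
                if f.include and not (terms & f.include):
                    ok = False
                    break
                if terms & f.exclude:
                    ok = False
                    break
            if ok:
                survivors.append((dcc, key, record))

    facet_counts = {facet: Counter() for facet in known}
    for dcc, key, record in survivors:
        idx = view.index(dcc)
        for facet in known:
            for term in idx.facet_terms[entity_type][facet].get(key, set()):
                facet_counts[facet][term] += 1
    return QueryResult(entity_type=entity_type,
                       records=[(dcc, r) for dcc, _, r in survivors],
                       facet_counts=facet_counts)


def _record_text_tokens(idx, entity, key, record):
    """All searchable text for one record, tokenised.

    Covers: term names/descriptions/synonyms attached directly; the
    record's own name/description-like fields; its project's and
    collections' names/descriptions plus terms attached to those
    collections; and terms attached to linked records (e.g. substances
    administered to a biosample's source subject).
    """
    texts = []

    def add_term_texts(terms):
        for term in terms:
            texts.extend(idx.term_text.get(term, ()))
            texts.append(term)

    add_term_texts(idx.all_terms(entity, key))
    for field_name in ("name", "description", "abbreviation", "filename"):
        value = record.get(field_name)
        if value:
            texts.append(value)

    ns, local = record.get("project_id_namespace"), record.get(
        "project_local_id")
    if ns and local:
        project = idx.records["project"].get(make_global_key(ns, local))
        if project:
            for f in ("name", "description", "abbreviation"):
                if project.get(f):
                    texts.append(project[f])

    for ckey in idx.collections_of.get(entity, {}).get(key, ()):
        coll = idx.records["collection"].get(ckey)
        if coll:
            for f in ("name", "description", "abbreviation"):
                if coll.get(f):
                    texts.append(coll[f])
        add_term_texts(idx.all_terms("collection", ckey))

    for other_entity, other_key in idx.linked.get(entity, {}).get(key, ()):
        add_term_texts(idx.all_terms(other_entity, other_key))

    out = set()
    for text in texts:
        out |= _tokens(text)
    return out


def query_keyword(view, entity_type, text):
    """Free-text search: whole-token, case-insensitive; all query tokens
    must be present in the record's associated text."""
    if entity_type not in ENTITY_TYPES:
        raise C2M2Error(errors.BAD_FACET, f"unknown entity {entity_type!r}")
    wanted = _tokens(text)
    if not wanted:
        raise ValueError("empty keyword")
    hits = []
    for dcc, idx in view.iter_indexes():
        for key, record in idx.records[entity_type].items():
            if wanted <= _record_text_tokens(idx, entity_type, key, record):
                hits.append((dcc, record))
    return QueryResult(entity_type=entity_type, records=hits, facet_counts={})


def browse_terms(view, text):
    """List term ids whose name, description or synonyms contain the word."""
    wanted = _tokens(text)
    found = set()
    for _, idx in view.iter_indexes():
        for term, fields in idx.term_text.items():
            if wanted <= set().union(*(_tokens(t) for t in fields)):
                found.add(term)
    return sorted(found)


def query_by_term(view, curie):
    """Every record associated with one CV term, grouped by entity type.

    Association is direct (the term on the record or an association row) or
    via containment (the record belongs to a collection annotated with the
    term; the collection itself is associated too).
    """
    known = any(curie in idx.term_text for _, idx in view.iter_indexes())
    if not known:
        raise C2M2Error(errors.UNKNOWN_TERM,
                        f"term {curie!r} is not in any term table of this "
                        "release")
    groups = {entity: [] for entity in ENTITY_TYPES}
    for dcc, idx in view.iter_indexes():
        annotated_collections = {
            key for key in idx.records["collection"]
            if curie in idx.all_terms("collection", key)}
        for entity in ENTITY_TYPES:
            for key, record in idx.records[entity].items():
                direct = curie in idx.all_terms(entity, key)
                via_collection = (
                    entity == "collection" and key in annotated_collections
                ) or bool(idx.collections_of.get(entity, {}).get(key, set())
                          & annotated_collections)
                if direct or via_collection:
                    groups[entity].append((dcc, record))
    return groups


# ---------------------------------------------------------------------------
# Statistics.
# ---------------------------------------------------------------------------

_ENTITY_LINK_TABLES = {
    ("file", "biosample"): [("file_describes_biosample", "file", "biosample")],
    ("file", "subject"): [("file_describes_subject", "file", "subject")],
    ("biosample", "subject"): [("biosample_from_subject", "biosample",
                                "subject")],
    ("file", "collection"): [("file_in_collection", "file", "collection"),
                             ("file_describes_collection", "file",
                              "collection")],
    ("biosample", "collection"): [("biosample_in_collection", "biosample",
                                   "collection")],
    ("subject", "collection"): [("subject_in_collection", "subject",
                                 "collection")],
}


def summary_stats(submission, registry=None):
    """Row counts and connectivity percentages for one submission.

    connectivity(A, B) = 100 * |{a in A with >= 1 link to B}| / |A|, with
    empty A reported as 0% and flagged.  A link is a direct association-table
    row or shared membership in a collection also containing a B record.
    Entity-to-term coverage (e.g. file -> data_type) counts records with the
    annotation present.
    """
    pkg = submission.package if isinstance(submission, Submission) else \
        submission
    idx = PackageIndex(pkg)
    row_counts = {name: len(pkg.tables[name].records)
                  for name in pkg.registry.list_tables()}
    connectivity = {}

    members_by_collection = {}
    for entity in ("file", "biosample", "subject"):
        for key, colls in idx.collections_of[entity].items():
            for ckey in colls:
                members_by_collection.setdefault(ckey, set()).add(
                    (entity, key))

    def entity_pair(a, b, link_tables):
        total = len(idx.records[a])
        if total == 0:
            connectivity[(a, b)] = ConnectivityStat(0.0, empty=True)
            return
        linked = set()
        for table_name, left, right in link_tables:
            for row in pkg.tables[table_name].records:
                linked.add(make_global_key(row[f"{left}_id_namespace"],
                                           row[f"{left}_local_id"]))
        if b == "collection":
            linked |= set(idx.collections_of[a])
        elif a == "collection":
            pass
        else:
            for key, colls in idx.collections_of.get(a, {}).items():
                for ckey in colls:
                    if any(e == b for e, _ in
                           members_by_collection.get(ckey, ())):
                        linked.add(key)
        linked &= set(idx.records[a])
        connectivity[(a, b)] = ConnectivityStat(100.0 * len(linked) / total)

    for (a, b), tables in _ENTITY_LINK_TABLES.items():
        entity_pair(a, b, tables)
        reverse = [(t, right, left) for t, left, right in tables]
        if b == "collection":
            total = len(idx.records["collection"])
            if total == 0:
                connectivity[(b, a)] = ConnectivityStat(0.0, empty=True)
            else:
                with_member = {
                    ckey for ckey, members in members_by_collection.items()
                    if any(e == a for e, _ in members)}
                with_member &= set(idx.records["collection"])
                connectivity[(b, a)] = ConnectivityStat(
                    100.0 * len(with_member) / total)
        else:
            entity_pair(b, a, reverse)

    # entity -> term-category coverage
    for entity, facets in FACETS.items():
        total = len(idx.records[entity])
        for facet in facets:
            annotated = sum(
                1 for key in idx.records[entity]
                if idx.facet_terms[entity][facet].get(key))
            connectivity[(entity, facet)] = (
                ConnectivityStat(0.0, empty=True) if total == 0 else
                ConnectivityStat(100.0 * annotated / total))
    return SummaryStats(row_counts=row_counts, connectivity=connectivity)


def compare_submissions(sub_a, sub_b):
    """Signed per-table count and connectivity deltas (B minus A)."""
    if sub_a.dcc != sub_b.dcc:
        raise C2M2Error(errors.BAD_COMPARISON,
                        "submissions to compare must come from one DCC "
                        f"({sub_a.dcc!r} vs {sub_b.dcc!r})")
    stats_a = summary_stats(sub_a)
    stats_b = summary_stats(sub_b)
    table_deltas = {
        name: stats_b.row_counts.get(name, 0) - stats_a.row_counts.get(name, 0)
        for name in sorted(set(stats_a.row_counts) | set(stats_b.row_counts))}
    conn_deltas = {}
    for key in sorted(set(stats_a.connectivity) | set(stats_b.connectivity)):
        pa = stats_a.connectivity.get(key, ConnectivityStat(0.0, True)).percent
        pb = stats_b.connectivity.get(key, ConnectivityStat(0.0, True)).percent
        conn_deltas[key] = pb - pa
    return StatsDelta(table_deltas=table_deltas, connectivity_deltas=conn_deltas)
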