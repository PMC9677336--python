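"""The C2M2 schema registry: 48 tables, their fields, keys and CV bindings.

The model describes biomedical research resources with six core entities —
files (digital bytestreams), biosamples (physical material), subjects
(organisms), projects and collections (containers), and the submitting DCC —
plus admin tables, association tables linking entities to each other and to
controlled-vocabulary terms, and one term table per supported vocabulary.
The registry is the single source of truth: TSV I/O, validation, fixtures
and the catalog all consume it.  It serialises to (and round-trips from) a
JSON package descriptor following the Frictionless Data Package layout.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from . import errors
from .errors import C2M2Error
from .vocab import VOCABULARIES, term_table_name

#: Version tag frozen with this table inventory; embedded in descriptors.
SCHEMA_VERSION = "2022.04"

DATATYPES = (
    "text", "integer", "non-negative-integer", "identifier", "curie",
    "uri", "timestamp",
)

TABLE_KINDS = ("core-entity", "container", "association", "term", "admin")

_NAME_RE = re.compile(r"[a-z][a-z0-9_]*\Z")


@dataclass(frozen=True)
class FieldSpec:
    """One column of one table."""

    name: str
    datatype: str = "text"
    required: bool = False
    cv_binding: str | None = None
    description: str = ""

    def __post_init__(self):
        if not _NAME_RE.match(self.name):
            raise ValueError(f"bad field name {self.name!r}")
        if self.datatype not in DATATYPES:
            raise ValueError(f"bad datatype {self.datatype!r}")
        if self.cv_binding is not None and self.cv_binding not in VOCABULARIES:
            raise ValueError(f"unknown vocabulary {self.cv_binding!r}")


@dataclass(frozen=True)
class ForeignKeySpec:
    source_table: str
    source_fields: tuple
    target_table: str
    target_fields: tuple

    def __post_init__(self):
        if len(self.source_fields) != len(self.target_fields):
            raise ValueError("foreign-key field lists differ in length")


@dataclass(frozen=True)
class TableSpec:
    name: str
    kind: str
    fields: tuple
    primary_key: tuple
    foreign_keys: tuple = ()

    def __post_init__(self):
        if self.kind not in TABLE_KINDS:
            raise ValueError(f"bad table kind {self.kind!r}")
        names = [f.name for f in self.fields]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate field names in {self.name}")
        for pk in self.primary_key:
            if pk not in names:
                raise ValueError(f"primary key {pk!r} not a field of {self.name}")
        if self.kind == "term" and names != ["id", "name", "description", "synonyms"]:
            raise ValueError("term tables carry exactly id/name/description/synonyms")

    @property
    def field_names(self):
        return tuple(f.name for f in self.fields)

    def field(self, name):
        for f in self.fields:
            if f.name == name:
                return f
        raise KeyError(name)


class SchemaRegistry:
    """An immutable, ordered set of :class:`TableSpec` under a version tag."""

    def __init__(self, version, tables):
        self.version = version
        self.tables = {t.name: t for t in tables}
        self._check_closure()

    def _check_closure(self):
        for table in self.tables.values():
            for fk in table.foreign_keys:
                target = self.tables.get(fk.target_table)
                if target is None:
                    raise ValueError(
                        f"{table.name}: foreign key targets unknown table "
                        f"{fk.target_table!r}")
                if tuple(fk.target_fields) != tuple(target.primary_key):
                    raise ValueError(
                        f"{table.name}: foreign key target fields must be the "
                        f"primary key of {fk.target_table}")

    def list_tables(self):
        """All table names, lexicographically sorted (deterministic)."""
        return sorted(self.tables)

    def table(self, name):
        try:
            return self.tables[name]
        except KeyError:
            raise C2M2Error(errors.UNKNOWN_TABLE, f"no table named {name!r}")

    def __eq__(self, other):
        return (isinstance(other, SchemaRegistry)
                and self.version == other.version
                and self.tables == other.tables)

    # -- descriptor ---------------------------------------------------------

    _FRICTIONLESS_TYPES = {
        "text": "string", "integer": "integer",
        "non-negative-integer": "integer", "identifier": "string",
        "curie": "string", "uri": "string", "timestamp": "datetime",
    }

    def emit_descriptor(self):
        """The registry as a Frictionless-style data-package descriptor."""
        resources = []
        for name in self.list_tables():
            table = self.tables[name]
            fields = []
            for f in table.fields:
                entry = {
                    "name": f.name,
                    "type": self._FRICTIONLESS_TYPES[f.datatype],
                    "constraints": {"required": f.required},
                    "description": f.description,
                    "c2m2:datatype": f.datatype,
                }
                if f.datatype == "non-negative-integer":
                    entry["constraints"]["minimum"] = 0
                if f.cv_binding is not None:
                    entry["c2m2:cvBinding"] = f.cv_binding
                fields.append(entry)
            schema = {"fields": fields, "primaryKey": list(table.primary_key)}
            if table.foreign_keys:
                schema["foreignKeys"] = [
                    {"fields": list(fk.source_fields),
                     "reference": {"resource": fk.target_table,
                                   "fields": list(fk.target_fields)}}
                    for fk in table.foreign_keys]
            resources.append({
                "profile": "tabular-data-resource",
                "name": name,
                "path": f"{name}.tsv",
                "dialect": {"delimiter": "\t"},
                "c2m2:kind": table.kind,
                "schema": schema,
            })
        return {
            "profile": "tabular-data-package",
            "name": "c2m2-datapackage",
            "version": self.version,
            "resources": resources,
        }

    @classmethod
    def from_descriptor(cls, descriptor):
        """Rebuild a registry from :meth:`emit_descriptor` output."""
        tables = []
        for resource in descriptor["resources"]:
            schema = resource["schema"]
            fields = tuple(
                FieldSpec(
                    name=f["name"],
                    datatype=f["c2m2:datatype"],
                    required=f.get("constraints", {}).get("required", False),
                    cv_binding=f.get("c2m2:cvBinding"),
                    description=f.get("description", ""),
                )
                for f in schema["fields"])
            fks = tuple(
                ForeignKeySpec(
                    source_table=resource["name"],
                    source_fields=tuple(fk["fields"]),
                    target_table=fk["reference"]["resource"],
                    target_fields=tuple(fk["reference"]["fields"]),
                )
                for fk in schema.get("foreignKeys", ()))
            tables.append(TableSpec(
                name=resource["name"],
                kind=resource["c2m2:kind"],
                fields=fields,
                primary_key=tuple(schema["primaryKey"]),
                foreign_keys=fks,
            ))
        return cls(version=descriptor["version"], tables=tables)

    def write_descriptor(self, path):
        Path(path).write_text(
            json.dumps(self.emit_descriptor(), indent=1, sort_keys=False) + "\n",
            encoding="utf-8")

    def make_stub_package(self, directory):
        """Write a header-only TSV per table plus the descriptor.

        A stub package is the starting point of every submission: one file
        per table keeps intentional emptiness distinguishable from
        accidental omission.  Returns the list of TSV paths.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for name in self.list_tables():
            table = self.tables[name]
            path = directory / f"{name}.tsv"
            path.write_text("\t".join(table.field_names) + "\n", encoding="utf-8")
            paths.append(path)
        self.write_descriptor(directory / "datapackage.json")
        return paths


# ---------------------------------------------------------------------------
# The default table inventory.
# ---------------------------------------------------------------------------

def _f(name, datatype="text", required=False, cv=None, desc=""):
    return FieldSpec(name, datatype=datatype, required=required,
                     cv_binding=cv, description=desc)


def _entity_core(with_project_link):
    fields = [
        _f("id_namespace", "identifier", required=True,
           desc="Namespace prefix of this record's C2M2 ID"),
        _f("local_id", "identifier", required=True,
           desc="Suffix of this record's C2M2 ID, unique within the namespace"),
    ]
    if with_project_link:
        fields += [
            _f("project_id_namespace", "identifier",
               desc="Namespace of the single project this record belongs to"),
            _f("project_local_id", "identifier",
               desc="Local id of the single project this record belongs to"),
        ]
    fields += [
        _f("persistent_id", "uri",
           desc="Optional resolvable persistent ID (DOI, minid, DRS, URI)"),
        _f("creation_time", "timestamp"),
    ]
    return fields


def _term_table(vocabulary):
    return TableSpec(
        name=term_table_name(vocabulary),
        kind="term",
        fields=(
            _f("id", "identifier", required=True,
               desc=f"{vocabulary} term id"),
            _f("name", "text", required=True),
            _f("description", "text"),
            _f("synonyms", "text", desc="Pipe-separated synonym list"),
        ),
        primary_key=("id",),
    )


def build_registry(version=SCHEMA_VERSION):
    """Construct the shipped 48-table registry.

    The inventory comprises the six core entities, three admin tables
    (id_namespace plus the subject_granularity / subject_role enumerations),
    nine container/provenance associations, twenty CV associations, and ten
    per-vocabulary term tables.
    """
    tables = []

    def entity(name, extra=(), with_project_link=True):
        fields = tuple(_entity_core(with_project_link) + list(extra))
        fks = []
        if with_project_link:
            fks.append(ForeignKeySpec(
                name, ("project_id_namespace", "project_local_id"),
                "project", ("id_namespace", "local_id")))
        tables.append(TableSpec(
            name=name, kind="container" if name in ("project", "collection")
            else "core-entity",
            fields=fields, primary_key=("id_namespace", "local_id"),
            foreign_keys=tuple(fks)))

    entity("file", extra=(
        _f("filename"),
        _f("size_in_bytes", "non-negative-integer"),
        _f("file_format", "curie", cv="EDAM",
           desc="Digital format of the file, e.g. FASTQ"),
        _f("compression_format", "curie", cv="EDAM"),
        _f("data_type", "curie", cv="EDAM",
           desc="Type of information contained in the file"),
        _f("assay_type", "curie", cv="OBI",
           desc="Type of experiment that produced the file"),
        _f("analysis_type", "curie", cv="OBI",
           desc="Analytic procedure that produced the file"),
        _f("mime_type"),
    ))
    entity("biosample", extra=(
        _f("name"),
        _f("description"),
        _f("assay_type", "curie", cv="OBI"),
        _f("anatomy", "curie", cv="UBERON",
           desc="Physiological source location of the sample"),
    ))
    entity("subject", extra=(
        _f("name"),
        _f("description"),
        _f("granularity", "identifier",
           desc="Single organism, cell line, microbiome, ..."),
    ))
    tables[-1] = TableSpec(
        name="subject", kind="core-entity", fields=tables[-1].fields,
        primary_key=tables[-1].primary_key,
        foreign_keys=tables[-1].foreign_keys + (
            ForeignKeySpec("subject", ("granularity",),
                           "subject_granularity", ("id",)),))

    # Containers: no project link columns (collections are grouped explicitly
    # via collection_defined_by_project; projects nest via project_in_project).
    entity("project", extra=(
        _f("name", required=True),
        _f("abbreviation"),
        _f("description"),
    ), with_project_link=False)
    entity("collection", extra=(
        _f("name"),
        _f("abbreviation"),
        _f("description"),
    ), with_project_link=False)

    tables.append(TableSpec(
        name="dcc", kind="core-entity",
        fields=(
            _f("id", "identifier", required=True),
            _f("dcc_name", required=True),
            _f("dcc_abbreviation", required=True),
            _f("dcc_description"),
            _f("contact_email", required=True),
            _f("contact_name", required=True),
            _f("dcc_url", "uri"),
            _f("project_id_namespace", "identifier", required=True,
               desc="Attribution project representing this DCC"),
            _f("project_local_id", "identifier", required=True),
        ),
        primary_key=("id",),
        foreign_keys=(ForeignKeySpec(
            "dcc", ("project_id_namespace", "project_local_id"),
            "project", ("id_namespace", "local_id")),),
    ))

    # Admin tables.
    tables.append(TableSpec(
        name="id_namespace", kind="admin",
        fields=(
            _f("id", "identifier", required=True,
               desc="Namespace token, registered in advance"),
            _f("abbreviation"),
            _f("name", required=True),
            _f("description"),
        ),
        primary_key=("id",),
    ))
    for admin in ("subject_granularity", "subject_role"):
        tables.append(TableSpec(
            name=admin, kind="admin",
            fields=(_f("id", "identifier", required=True),
                    _f("name", required=True),
                    _f("description")),
            primary_key=("id",),
        ))

    # Container & provenance associations.
    def pair_assoc(name, left, left_table, right, right_table):
        fields = (
            _f(f"{left}_id_namespace", "identifier", required=True),
            _f(f"{left}_local_id", "identifier", required=True),
            _f(f"{right}_id_namespace", "identifier", required=True),
            _f(f"{right}_local_id", "identifier", required=True),
        )
        tables.append(TableSpec(
            name=name, kind="association", fields=fields,
            primary_key=tuple(f.name for f in fields),
            foreign_keys=(
                ForeignKeySpec(name,
                               (f"{left}_id_namespace", f"{left}_local_id"),
                               left_table, ("id_namespace", "local_id")),
                ForeignKeySpec(name,
                               (f"{right}_id_namespace", f"{right}_local_id"),
                               right_table, ("id_namespace", "local_id")),
            )))

    pair_assoc("project_in_project", "parent_project", "project",
               "child_project", "project")
    pair_assoc("collection_in_collection", "superset_collection", "collection",
               "subset_collection", "collection")
    pair_assoc("file_in_collection", "file", "file", "collection", "collection")
    pair_assoc("biosample_in_collection", "biosample", "biosample",
               "collection", "collection")
    pair_assoc("subject_in_collection", "subject", "subject",
               "collection", "collection")
    pair_assoc("collection_defined_by_project", "collection", "collection",
               "project", "project")
    pair_assoc("file_describes_biosample", "file", "file",
               "biosample", "biosample")
    pair_assoc("file_describes_subject", "file", "file", "subject", "subject")
    pair_assoc("file_describes_collection", "file", "file",
               "collection", "collection")
    pair_assoc("biosample_from_subject", "biosample", "biosample",
               "subject", "subject")

    # Entity-to-term CV associations (Table 2 bindings).
    def cv_assoc(name, entity_name, term_field, vocabulary, extra_fk=()):
        fields = (
            _f(f"{entity_name}_id_namespace", "identifier", required=True),
            _f(f"{entity_name}_local_id", "identifier", required=True),
            _f(term_field,
               "identifier" if vocabulary in ("Ensembl", "UniProtKB") else "curie",
               required=True, cv=vocabulary),
        ) + tuple(extra_fk)
        tables.append(TableSpec(
            name=name, kind="association", fields=fields,
            primary_key=tuple(f.name for f in fields),
            foreign_keys=(
                ForeignKeySpec(
                    name, (f"{entity_name}_id_namespace", f"{entity_name}_local_id"),
                    entity_name, ("id_namespace", "local_id")),),
        ))

    cv_assoc("subject_phenotype", "subject", "phenotype", "HPO")
    cv_assoc("collection_phenotype", "collection", "phenotype", "HPO")
    cv_assoc("biosample_disease", "biosample", "disease", "DiseaseOntology")
    cv_assoc("subject_disease", "subject", "disease", "DiseaseOntology")
    cv_assoc("collection_disease", "collection", "disease", "DiseaseOntology")
    cv_assoc("biosample_gene", "biosample", "gene", "Ensembl")
    cv_assoc("collection_gene", "collection", "gene", "Ensembl")
    cv_assoc("biosample_substance", "biosample", "substance", "PubChem")
    cv_assoc("subject_substance", "subject", "substance", "PubChem")
    cv_assoc("collection_substance", "collection", "substance", "PubChem")
    cv_assoc("collection_compound", "collection", "compound", "PubChem")
    cv_assoc("collection_taxonomy", "collection", "taxon", "NCBITaxonomy")
    cv_assoc("collection_protein", "collection", "protein", "UniProtKB")
    cv_assoc("collection_anatomy", "collection", "anatomy", "UBERON")

    tables.append(TableSpec(
        name="subject_role_taxonomy", kind="association",
        fields=(
            _f("subject_id_namespace", "identifier", required=True),
            _f("subject_local_id", "identifier", required=True),
            _f("role_id", "identifier", required=True),
            _f("taxonomy_id", "curie", required=True, cv="NCBITaxonomy"),
        ),
        primary_key=("subject_id_namespace", "subject_local_id",
                     "role_id", "taxonomy_id"),
        foreign_keys=(
            ForeignKeySpec("subject_role_taxonomy",
                           ("subject_id_namespace", "subject_local_id"),
                           "subject", ("id_namespace", "local_id")),
            ForeignKeySpec("subject_role_taxonomy", ("role_id",),
                           "subject_role", ("id",)),
        )))

    # Term-to-term associations.
    def term_pair(name, left_field, left_vocab, right_field, right_vocab):
        fields = (
            _f(left_field,
               "identifier" if left_vocab in ("Ensembl", "UniProtKB") else "curie",
               required=True, cv=left_vocab),
            _f(right_field,
               "identifier" if right_vocab in ("Ensembl", "UniProtKB") else "curie",
               required=True, cv=right_vocab),
        )
        tables.append(TableSpec(
            name=name, kind="association", fields=fields,
            primary_key=(left_field, right_field)))

    term_pair("protein_gene", "protein", "UniProtKB", "gene", "Ensembl")
    term_pair("phenotype_gene", "phenotype", "HPO", "gene", "Ensembl")
    term_pair("phenotype_disease", "phenotype", "HPO", "disease",
              "DiseaseOntology")
    term_pair("substance_compound", "substance", "PubChem", "compound",
              "PubChem")

    for vocabulary in VOCABULARIES:
        tables.append(_term_table(vocabulary))

    registry = SchemaRegistry(version=version, tables=tables)
    assert len(registry.tables) == 48, len(registry.tables)
    return registry
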