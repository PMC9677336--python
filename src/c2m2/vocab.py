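"""Controlled vocabularies: CURIE detection, reference files, term tables.

C2M2 metadata cells refer to ontology terms either as CURIEs
(``PREFIX:LOCAL``, e.g. ``UBERON:0000178``) or, for Ensembl genes and
UniProtKB proteins, as bare accessions.  This module holds the prefix
registry, the reference-file reader/writer (a simple TSV: id, name,
description, synonyms, obsolete, replaced_by), the scan that collects every
term used anywhere in a data package, and the builder that turns that scan
into per-vocabulary term tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from . import errors
from .errors import C2M2Error

#: Vocabularies supported by the model, one term table each.
VOCABULARIES = (
    "OBI",
    "EDAM",
    "UBERON",
    "DiseaseOntology",
    "NCBITaxonomy",
    "Ensembl",
    "PubChem",
    "GlyTouCan",
    "HPO",
    "UniProtKB",
)

#: CURIE prefixes owned by each vocabulary (case-sensitive canonical forms).
#: Ensembl and UniProtKB use bare accessions instead of CURIEs.
VOCAB_PREFIXES = {
    "OBI": frozenset({"OBI"}),
    "EDAM": frozenset({"EDAM"}),
    "UBERON": frozenset({"UBERON"}),
    "DiseaseOntology": frozenset({"DOID"}),
    "NCBITaxonomy": frozenset({"NCBITaxon"}),
    "Ensembl": frozenset(),
    "PubChem": frozenset({"PUBCHEM"}),
    "GlyTouCan": frozenset({"GLYTOUCAN"}),
    "HPO": frozenset({"HP"}),
    "UniProtKB": frozenset(),
}

#: Prefixes recognised as CURIEs even though no C2M2 field binds to them
#: (free-text cells in the wild cite these; detection must still see them).
EXTRA_PREFIXES = frozenset({"ENVO", "GO", "CHEBI", "CL", "MONDO", "EFO"})

REGISTERED_PREFIXES = frozenset().union(*VOCAB_PREFIXES.values(), EXTRA_PREFIXES)

#: Accession patterns for the two non-CURIE vocabularies.
ACCESSION_PATTERNS = {
    "Ensembl": re.compile(r"ENS[A-Z]{0,5}[GTP]\d{11}(\.\d+)?\Z"),
    "UniProtKB": re.compile(
        r"(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})\Z"
    ),
}

_CURIE_RE = re.compile(r"([A-Za-z][A-Za-z0-9.]*):([^\s:]+)\Z")


def detect_curie(value):
    """Parse ``value`` as a CURIE, returning ``(prefix, local)`` or ``None``.

    Total over text cells: anything that is not a whole-string
    ``PREFIX:LOCAL`` match with a registered prefix is simply not a CURIE.
    Prefix matching is case-sensitive on the canonical registered form.
    """
    if value is None:
        return None
    m = _CURIE_RE.match(value)
    if m is None:
        return None
    prefix, local = m.group(1), m.group(2)
    if prefix not in REGISTERED_PREFIXES:
        return None
    return prefix, local


def term_id_matches_vocabulary(vocabulary, value):
    """True when ``value`` is a well-formed term id for ``vocabulary``."""
    pattern = ACCESSION_PATTERNS.get(vocabulary)
    if pattern is not None:
        return bool(pattern.match(value))
    parsed = detect_curie(value)
    return parsed is not None and parsed[0] in VOCAB_PREFIXES[vocabulary]


@dataclass(frozen=True)
class TermRecord:
    """One controlled-vocabulary term as carried by a reference file."""

    id: str
    name: str
    description: str = ""
    synonyms: tuple = ()
    obsolete: bool = False
    replaced_by: str | None = None
    provisional: bool = False


@dataclass
class VocabularyRef:
    """A term reference for one vocabulary: id -> :class:`TermRecord`."""

    vocabulary: str
    version: str = ""
    terms: dict = field(default_factory=dict)

    def add(self, record):
        self.terms[record.id] = record


_REF_COLUMNS = ("id", "name", "description", "synonyms", "obsolete", "replaced_by")
_PROVISIONAL_COLUMNS = ("id", "name", "description", "synonyms")


def write_reference(ref, path):
    """Write a ``<vocabulary>.ref.tsv`` reference file (synonyms pipe-joined)."""
    lines = ["\t".join(_REF_COLUMNS)]
    for term_id in sorted(ref.terms):
        t = ref.terms[term_id]
        lines.append("\t".join([
            t.id, t.name, t.description, "|".join(t.synonyms),
            "true" if t.obsolete else "false", t.replaced_by or "",
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_reference(path, vocabulary, version=""):
    """Read a reference TSV into a :class:`VocabularyRef`."""
    ref = VocabularyRef(vocabulary=vocabulary, version=version)
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines or tuple(lines[0].split("\t")) != _REF_COLUMNS:
        raise C2M2Error(errors.BAD_HEADER,
                        f"reference file {path} must start with {_REF_COLUMNS}")
    for line in lines[1:]:
        cells = line.split("\t")
        if len(cells) != len(_REF_COLUMNS):
            raise C2M2Error(errors.BAD_ROW, f"malformed reference row in {path}")
        term_id, name, description, synonyms, obsolete, replaced = cells
        ref.add(TermRecord(
            id=term_id, name=name, description=description,
            synonyms=tuple(s for s in synonyms.split("|") if s),
            obsolete=obsolete.lower() == "true",
            replaced_by=replaced or None,
        ))
    return ref


def write_provisional(records, vocabulary, directory):
    """Write the ``<vocabulary>.provisional.tsv`` sidecar."""
    lines = ["\t".join(_PROVISIONAL_COLUMNS)]
    for t in sorted(records, key=lambda t: t.id):
        lines.append("\t".join([t.id, t.name, t.description, "|".join(t.synonyms)]))
    path = Path(directory) / f"{vocabulary}.provisional.tsv"
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_provisional(path, vocabulary):
    ref = VocabularyRef(vocabulary=vocabulary)
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or tuple(lines[0].split("\t")) != _PROVISIONAL_COLUMNS:
        raise C2M2Error(errors.BAD_HEADER,
                        f"provisional file {path} must start with {_PROVISIONAL_COLUMNS}")
    for line in lines[1:]:
        term_id, name, description, synonyms = line.split("\t")
        ref.add(TermRecord(
            id=term_id, name=name, description=description,
            synonyms=tuple(s for s in synonyms.split("|") if s),
            provisional=True,
        ))
    return ref


def load_references(directory):
    """Load every ``*.ref.tsv`` (and provisional sidecar) in ``directory``.

    Returns ``(refs, provisional)``, both vocabulary -> VocabularyRef.
    """
    directory = Path(directory)
    refs, provisional = {}, {}
    for vocabulary in VOCABULARIES:
        ref_path = directory / f"{vocabulary}.ref.tsv"
        if ref_path.exists():
            refs[vocabulary] = read_reference(ref_path, vocabulary)
        prov_path = directory / f"{vocabulary}.provisional.tsv"
        if prov_path.exists():
            provisional[vocabulary] = read_provisional(prov_path, vocabulary)
    return refs, provisional


def cv_columns(registry):
    """Yield ``(table_name, field_name, vocabulary)`` for every CV-bound column.

    Term tables themselves are excluded: their id columns enumerate usage,
    they do not constitute it (this is what makes term-table building
    idempotent).
    """
    for table in registry.tables.values():
        if table.kind == "term":
            continue
        for f in table.fields:
            if f.cv_binding is not None:
                yield table.name, f.name, f.cv_binding


def collect_used_terms(pkg, registry, issues=None):
    """Scan every CV-bound cell of ``pkg`` and route terms to vocabularies.

    Returns vocabulary -> set of term ids.  Malformed cells (a CURIE whose
    prefix belongs to a different vocabulary than the column binding, a
    non-CURIE in a CURIE-bound column, a malformed accession) are reported
    as WRONG_VOCABULARY: appended to ``issues`` when a list is supplied,
    raised otherwise.  Flagged cells are excluded from the returned sets.
    """
    used = {v: set() for v in VOCABULARIES}
    for table_name, field_name, vocabulary in cv_columns(registry):
        table = pkg.tables.get(table_name)
        if table is None:
            continue
        for line, record in table.numbered_records():
            value = record.get(field_name)
            if value is None:
                continue
            if term_id_matches_vocabulary(vocabulary, value):
                used[vocabulary].add(value)
                continue
            err = C2M2Error(
                errors.WRONG_VOCABULARY,
                f"value {value!r} is not a valid {vocabulary} term id "
                f"for {table_name}.{field_name}",
                table=table_name, row=line, field=field_name)
            if issues is None:
                raise err
            issues.append(err)
    return used


def term_table_name(vocabulary):
    """Name of the term table backing ``vocabulary`` (snake-cased)."""
    return re.sub(r"(?<=[a-z0-9])(?=[A-Z])", "_", vocabulary).lower()


def build_term_tables(pkg, refs, provisional=None, issues=None):
    """Populate the per-vocabulary term tables of ``pkg`` in place.

    One row per term used anywhere in the submission, with name,
    description and synonyms imported from the reference files; vocabularies
    with no used terms end up as header-only tables.  Provisional terms
    (declared in the sidecar) are accepted before they reach the reference
    release; obsolete reference terms remain usable so legacy submissions
    keep validating, with ``replaced_by`` available from the reference.

    Terms found in neither source raise (or append) UNKNOWN_TERM.
    Idempotent: the scan never reads term tables, so rebuilding on the
    output is a no-op.  Returns the used-term map.
    """
    provisional = provisional or {}
    used = collect_used_terms(pkg, pkg.registry, issues=issues)
    for vocabulary in VOCABULARIES:
        rows = []
        ref = refs.get(vocabulary)
        prov = provisional.get(vocabulary)
        for term_id in sorted(used[vocabulary]):
            record = None
            if ref is not None:
                record = ref.terms.get(term_id)
            if record is None and prov is not None:
                record = prov.terms.get(term_id)
            if record is None:
                err = C2M2Error(
                    errors.UNKNOWN_TERM,
                    f"term {term_id!r} ({vocabulary}) is not in the reference "
                    "files and was not declared provisional",
                    table=term_table_name(vocabulary))
                if issues is None:
                    raise err
                issues.append(err)
                continue
            rows.append({
                "id": record.id,
                "name": record.name,
                "description": record.description or None,
                "synonyms": "|".join(record.synonyms) or None,
            })
        pkg.tables[term_table_name(vocabulary)].records = rows
    return used


def term_records_in_package(pkg, refs, provisional=None):
    """Resolve the term-table rows of ``pkg`` back to :class:`TermRecord`.

    Returns vocabulary -> {id: TermRecord}, with provisional/obsolete flags
    recovered from the references; rows absent from both sources are kept as
    bare records so search still sees their names.
    """
    provisional = provisional or {}
    out = {}
    for vocabulary in VOCABULARIES:
        table = pkg.tables.get(term_table_name(vocabulary))
        resolved = {}
        if table is not None:
            for record in table.records:
                term_id = record["id"]
                ref = refs.get(vocabulary)
                prov = provisional.get(vocabulary)
                full = ref.terms.get(term_id) if ref else None
                if full is None and prov is not None:
                    full = prov.terms.get(term_id)
                if full is None:
                    full = TermRecord(
                        id=term_id, name=record.get("name") or "",
                        description=record.get("description") or "",
                        synonyms=tuple((record.get("synonyms") or "").split("|"))
                        if record.get("synonyms") else (),
                    )
                resolved[term_id] = full
        out[vocabulary] = resolved
    return out
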