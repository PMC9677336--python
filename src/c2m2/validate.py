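"""Deep validation of a data package: structure, relations, vocabulary.

Checks run in a fixed order and accumulate issues instead of raising, so a
single pass reports everything wrong with a submission:

1. every registry table file present (stub rule);
2. headers, row shapes, datatypes, required cells;
3. primary-key uniqueness per table;
4. foreign-key integrity across tables;
5. the three strictly required records — a DCC contact record, a single
   attribution project, and at least one pre-registered id_namespace;
6. every file/biosample/subject linked to exactly one project (containers
   are exempt: they group records, they are not experimental resources);
7. every controlled-vocabulary term known to the references or declared
   provisional;
8. term tables exactly matching the set of used terms.

A package is valid iff no error-severity issue was produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

from . import errors, tsv, vocab
from .errors import C2M2Error

ERROR = "error"
WARNING = "warning"

#: Codes reported at warning severity; everything else is an error.
_WARNING_CODES = frozenset({errors.UNKNOWN_TABLE})

#: Entities whose records must each belong to exactly one project.
PROJECT_LINKED_ENTITIES = ("file", "biosample", "subject")

#: Entity tables whose id_namespace column must be registered (rule 5c/6).
NAMESPACED_ENTITIES = ("file", "biosample", "subject", "project", "collection")


@dataclass(frozen=True)
class ValidationIssue:
    code: str
    severity: str
    table: str | None = None
    row: int | None = None
    field: str | None = None
    message: str = ""

    def to_dict(self):
        return {"code": self.code, "severity": self.severity,
                "table": self.table, "row": self.row, "field": self.field,
                "message": self.message}


@dataclass
class ValidationReport:
    issues: list = dc_field(default_factory=list)

    @property
    def valid(self):
        return not any(i.severity == ERROR for i in self.issues)

    def codes(self):
        """Distinct error codes present, in first-appearance order."""
        seen = []
        for issue in self.issues:
            if issue.severity == ERROR and issue.code not in seen:
                seen.append(issue.code)
        return seen

    def add(self, code, message, *, table=None, row=None, field=None,
            severity=None):
        if severity is None:
            severity = WARNING if code in _WARNING_CODES else ERROR
        self.issues.append(ValidationIssue(
            code=code, severity=severity, table=table, row=row, field=field,
            message=message))

    def extend_from_errors(self, errs):
        for e in errs:
            self.add(e.code, e.message, table=e.table, row=e.row, field=e.field)

    def to_json_lines(self):
        import json
        return "\n".join(json.dumps(i.to_dict()) for i in self.issues)


def _pk_tuple(record, pk_fields):
    return tuple(record.get(f) for f in pk_fields)


def _check_duplicate_pks(pkg, report):
    for name in pkg.registry.list_tables():
        table = pkg.tables.get(name)
        if table is None:
            continue
        seen = {}
        for line, record in table.numbered_records():
            key = _pk_tuple(record, table.spec.primary_key)
            if None in key:
                continue  # missing PK cells already reported as MISSING_VALUE
            if key in seen:
                report.add(errors.DUPLICATE_PK,
                           f"primary key {key!r} first used on line "
                           f"{seen[key]} is repeated",
                           table=name, row=line)
            else:
                seen[key] = line
    return report


def _check_foreign_keys(pkg, report):
    key_sets = {}

    def target_keys(table_name, fields):
        cache_key = (table_name, fields)
        if cache_key not in key_sets:
            table = pkg.tables.get(table_name)
            key_sets[cache_key] = (
                set() if table is None else
                {_pk_tuple(r, fields) for r in table.records})
        return key_sets[cache_key]

    for name in pkg.registry.list_tables():
        table = pkg.tables.get(name)
        if table is None:
            continue
        for fk in table.spec.foreign_keys:
            targets = target_keys(fk.target_table, tuple(fk.target_fields))
            for line, record in table.numbered_records():
                source = tuple(record.get(f) for f in fk.source_fields)
                if all(v is None for v in source):
                    continue  # wholly-null FK is simply absent
                if source not in targets:
                    report.add(
                        errors.FK_VIOLATION,
                        f"{fk.source_fields} = {source!r} has no matching "
                        f"record in {fk.target_table}",
                        table=name, row=line, field=fk.source_fields[0])
    return report


def _check_required_records(pkg, report):
    requirements = (
        ("dcc", "a contact record referencing the submitting DCC"),
        ("project", "a project record representing the submitting DCC "
                    "(resource attribution)"),
        ("id_namespace", "an ID namespace registered in advance"),
    )
    for table_name, what in requirements:
        table = pkg.tables.get(table_name)
        if table is None or not table.records:
            report.add(errors.MISSING_REQUIRED_RECORD,
                       f"submission must contain {what}", table=table_name)
    return report


def _check_project_links(pkg, report):
    for name in PROJECT_LINKED_ENTITIES:
        table = pkg.tables.get(name)
        if table is None:
            continue
        for line, record in table.numbered_records():
            ns = record.get("project_id_namespace")
            local = record.get("project_local_id")
            if ns is None or local is None:
                report.add(
                    errors.ORPHAN_ENTITY,
                    f"{name} record is not linked to a project (every "
                    "tangible experimental resource must belong to exactly "
                    "one)", table=name, row=line, field="project_local_id")
    return report


def _check_namespaces(pkg, report):
    ns_table = pkg.tables.get("id_namespace")
    registered = (set() if ns_table is None else
                  {r.get("id") for r in ns_table.records} - {None})
    for name in NAMESPACED_ENTITIES:
        table = pkg.tables.get(name)
        if table is None:
            continue
        for line, record in table.numbered_records():
            ns = record.get("id_namespace")
            if ns is not None and ns not in registered:
                report.add(errors.NAMESPACE_UNREGISTERED,
                           f"id_namespace {ns!r} has no registration record",
                           table=name, row=line, field="id_namespace")
    return report


def _check_terms(pkg, refs, provisional, report):
    """Rules 7 and 8.

    Terms already flagged (unknown or mis-vocabularied) are excluded from
    the rule-8 comparison so each defect is reported under exactly one code.
    """
    cv_issues = []
    used = vocab.collect_used_terms(pkg, pkg.registry, issues=cv_issues)
    report.extend_from_errors(cv_issues)

    for vocabulary in vocab.VOCABULARIES:
        ref = refs.get(vocabulary)
        prov = provisional.get(vocabulary) if provisional else None
        known_used = set()
        for term in sorted(used[vocabulary]):
            in_ref = ref is not None and term in ref.terms
            in_prov = prov is not None and term in prov.terms
            if not in_ref and not in_prov:
                report.add(
                    errors.UNKNOWN_TERM,
                    f"term {term!r} ({vocabulary}) is neither in the "
                    "reference files nor declared provisional",
                    table=vocab.term_table_name(vocabulary))
            else:
                known_used.add(term)

        table = pkg.tables.get(vocab.term_table_name(vocabulary))
        listed = (set() if table is None else
                  {r.get("id") for r in table.records} - {None})
        missing = sorted(known_used - listed)
        extra = sorted(listed - known_used)
        if missing or extra:
            parts = []
            if missing:
                parts.append(f"used but not listed: {missing}")
            if extra:
                parts.append(f"listed but never used: {extra}")
            report.add(errors.TERM_TABLE_MISMATCH,
                       f"{vocabulary} term table does not equal the used-term "
                       f"set ({'; '.join(parts)})",
                       table=vocab.term_table_name(vocabulary))
    return report


def lightweight_validate(directory, registry):
    """Stage-one validation: file inventory, headers, rows, keys.

    This is the pre-upload check the bundler runs; it is a strict subset of
    :func:`validate_package`, so anything passing deep validation passes
    here too.
    """
    report = ValidationReport()
    issues = []
    pkg = tsv.read_package(directory, registry, issues=issues)
    report.extend_from_errors(
        [e for e in issues if e.code != errors.UNKNOWN_TABLE])
    for e in issues:
        if e.code == errors.UNKNOWN_TABLE:
            report.add(e.code, e.message, table=e.table)
    _check_duplicate_pks(pkg, report)
    return pkg, report


def validate_package(package, registry=None, refs=None, provisional=None):
    """Validate a package directory or in-memory :class:`tsv.DataPackage`.

    Returns a :class:`ValidationReport`; problems are reported as issues,
    never raised (an unreadable directory is the one exception).  The
    package is never modified.
    """
    refs = refs or {}
    if isinstance(package, (str, Path)):
        if registry is None:
            raise ValueError("registry required when validating a directory")
        if not Path(package).is_dir():
            raise FileNotFoundError(f"{package} is not a directory")
        pkg, report = lightweight_validate(package, registry)
    else:
        pkg = package
        report = ValidationReport()
        _check_duplicate_pks(pkg, report)

    _check_foreign_keys(pkg, report)
    _check_required_records(pkg, report)
    _check_project_links(pkg, report)
    _check_namespaces(pkg, report)
    _check_terms(pkg, refs, provisional or {}, report)
    return report
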