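"""Strict TSV reading and writing for C2M2 table files.

The dialect is deliberately rigid so that serialisation is canonical and
packages can be compared by checksum: UTF-8, Unix newlines, no quoting, one
``<table>.tsv`` per registry table, header line exactly equal to the schema
field order.  Values containing literal tabs, carriage returns or newlines
are rejected outright rather than escaped.  Empty cells are nulls for
optional fields and MISSING_VALUE errors for required ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

from . import errors
from .errors import C2M2Error

_FORBIDDEN = ("\t", "\n", "\r")


@dataclass
class Table:
    """One parsed table: a spec plus ordered records (field -> str | None)."""

    spec: object
    records: list = dc_field(default_factory=list)

    def numbered_records(self):
        """Yield ``(line_number, record)`` with the header as line 1."""
        for i, record in enumerate(self.records):
            yield i + 2, record

    def __eq__(self, other):
        return (isinstance(other, Table) and self.spec == other.spec
                and self.records == other.records)


@dataclass
class DataPackage:
    """An in-memory submission: every registry table, stubs included."""

    registry: object
    tables: dict = dc_field(default_factory=dict)

    @classmethod
    def empty(cls, registry):
        return cls(registry=registry,
                   tables={name: Table(spec=registry.tables[name])
                           for name in registry.list_tables()})

    @property
    def registry_version(self):
        return self.registry.version

    @property
    def descriptor(self):
        return self.registry.emit_descriptor()

    def total_records(self):
        return sum(len(t.records) for t in self.tables.values())

    def __eq__(self, other):
        return (isinstance(other, DataPackage)
                and self.registry == other.registry
                and self.tables == other.tables)


def _check_value(value, table_name, line, field_name):
    for ch in _FORBIDDEN:
        if ch in value:
            raise C2M2Error(
                errors.BAD_ROW,
                f"value contains a literal {ch!r}; the dialect forbids it",
                table=table_name, row=line, field=field_name)


def _typecheck(value, fspec):
    """True when ``value`` is acceptable for the field's datatype.

    CURIE cells are only shape-checked here; vocabulary routing is the term
    machinery's job and gets its own issue code.
    """
    dt = fspec.datatype
    if dt == "integer":
        try:
            int(value)
        except ValueError:
            return False
    elif dt == "non-negative-integer":
        try:
            return int(value) >= 0
        except ValueError:
            return False
    elif dt == "identifier":
        return value == value.strip() and value != ""
    elif dt == "timestamp":
        return value == value.strip() and value != ""
    return True


def read_table(path, spec, issues=None):
    """Parse one TSV against ``spec``.

    With ``issues=None`` the first problem raises; with a list supplied,
    problems are appended as :class:`C2M2Error` and parsing continues (rows
    that cannot be aligned to the header are dropped).  Errors carry 1-based
    line numbers counting the header line as 1.
    """
    path = Path(path)

    def problem(err):
        if issues is None:
            raise err
        issues.append(err)

    text = path.read_text(encoding="utf-8")
    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if not lines:
        problem(C2M2Error(errors.BAD_HEADER, f"{path.name} is empty",
                          table=spec.name, row=1))
        return Table(spec=spec)
    header = tuple(lines[0].split("\t"))
    if header != spec.field_names:
        problem(C2M2Error(
            errors.BAD_HEADER,
            f"header of {path.name} is {header!r}, expected "
            f"{spec.field_names!r} (order-exact)",
            table=spec.name, row=1))
        return Table(spec=spec)

    table = Table(spec=spec)
    for i, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(spec.field_names):
            problem(C2M2Error(
                errors.BAD_ROW,
                f"line {i} has {len(cells)} cells, expected "
                f"{len(spec.field_names)}",
                table=spec.name, row=i))
            continue
        record = {}
        for fspec, cell in zip(spec.fields, cells):
            if cell == "":
                if fspec.required:
                    problem(C2M2Error(
                        errors.MISSING_VALUE,
                        f"required field {fspec.name!r} is empty",
                        table=spec.name, row=i, field=fspec.name))
                record[fspec.name] = None
            else:
                if not _typecheck(cell, fspec):
                    problem(C2M2Error(
                        errors.BAD_ROW,
                        f"value {cell!r} is not a valid {fspec.datatype}",
                        table=spec.name, row=i, field=fspec.name))
                record[fspec.name] = cell
        table.records.append(record)
    return table


def write_table(table, path):
    """Serialise one table canonically (schema field order, LF, UTF-8)."""
    spec = table.spec
    lines = ["\t".join(spec.field_names)]
    for line_no, record in table.numbered_records():
        extra = set(record) - set(spec.field_names)
        if extra:
            raise C2M2Error(
                errors.BAD_ROW,
                f"record carries fields {sorted(extra)} unknown to "
                f"{spec.name}", table=spec.name, row=line_no)
        cells = []
        for name in spec.field_names:
            value = record.get(name)
            if value is None:
                value = ""
            _check_value(value, spec.name, line_no, name)
            cells.append(value)
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    return Path(path)


def write_package(pkg, directory):
    """Write every registry table (stubs for empty ones) plus the descriptor.

    Canonical: a given package always produces byte-identical files, so two
    directories can be compared by checksum.  Returns the written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in pkg.registry.list_tables():
        table = pkg.tables.get(name) or Table(spec=pkg.registry.tables[name])
        paths.append(write_table(table, directory / f"{name}.tsv"))
    pkg.registry.write_descriptor(directory / "datapackage.json")
    return paths


def read_package(directory, registry, issues=None):
    """Read a package directory back into a :class:`DataPackage`.

    Every registry table must be present (MISSING_TABLE otherwise; the
    stub-file rule distinguishes intentional emptiness from omission).
    Unrecognised ``*.tsv`` files yield an UNKNOWN_TABLE warning appended to
    ``issues`` when a list is supplied.  With ``issues=None``, the first
    error raises.
    """
    directory = Path(directory)
    pkg = DataPackage.empty(registry)

    def problem(err):
        if issues is None:
            raise err
        issues.append(err)

    expected = set(registry.list_tables())
    for path in sorted(directory.glob("*.tsv")):
        if path.stem not in expected:
            if issues is not None:
                issues.append(C2M2Error(
                    errors.UNKNOWN_TABLE,
                    f"unrecognised table file {path.name}", table=path.stem))
    for name in registry.list_tables():
        path = directory / f"{name}.tsv"
        if not path.exists():
            problem(C2M2Error(errors.MISSING_TABLE,
                              f"table file {name}.tsv is missing (stub "
                              "required even when empty)", table=name))
            continue
        pkg.tables[name] = read_table(path, registry.tables[name], issues=issues)
    return pkg
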