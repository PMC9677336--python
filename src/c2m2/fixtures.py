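"""Synthetic data packages, mini-ontologies and seeded-defect fixtures.

Everything the toolchain needs for offline testing is generated here:
deterministic data packages with known planted annotations (so query and
connectivity results have an exact ground truth), miniature vocabularies
with ``is_a`` DAGs and slims, packages carrying exactly one planted
validation defect per issue code, and the key/value cells of the published
five-program metadata comparison table.

Determinism: every artifact kind draws from its own pseudo-random stream
derived from the single config seed, so identical configs yield
byte-identical packages and adding new artifact kinds later cannot shift
existing output.  Annotation rates are planted exactly — a rate r over n
records places round(r*n) annotations, never a Bernoulli draw — so
connectivity statistics are exact, not stochastic.
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from . import errors, slim as slim_mod, tsv, vocab
from .errors import C2M2Error
from .schema import build_registry
from .vocab import VOCABULARIES, VOCAB_PREFIXES, TermRecord, VocabularyRef

#: Facet -> annotation rate used when the config does not override it.
DEFAULT_RATES = {
    "file.file_format": 1.0,
    "file.data_type": 0.8,
    "file.assay_type": 0.6,
    "file.compression_format": 0.3,
    "file.analysis_type": 0.2,
    "biosample.anatomy": 1.0,
    "biosample.assay_type": 0.6,
    "biosample_disease": 0.4,
    "biosample_substance": 0.3,
    "biosample_gene": 0.2,
    "subject_disease": 0.4,
    "subject_substance": 0.3,
    "subject_phenotype": 0.4,
    "collection_anatomy": 0.6,
    "collection_disease": 0.3,
    "collection_substance": 0.2,
    "file_describes_biosample": 0.6,
}

#: Issue codes the defect injector can plant (the full validation set).
INJECTABLE_CODES = errors.VALIDATION_CODES

_FACET_VOCAB = {
    "file.file_format": "EDAM", "file.data_type": "EDAM",
    "file.compression_format": "EDAM", "file.assay_type": "OBI",
    "file.analysis_type": "OBI", "biosample.anatomy": "UBERON",
    "biosample.assay_type": "OBI",
    "biosample_disease": "DiseaseOntology", "subject_disease": "DiseaseOntology",
    "collection_disease": "DiseaseOntology",
    "biosample_substance": "PubChem", "subject_substance": "PubChem",
    "collection_substance": "PubChem",
    "biosample_gene": "Ensembl",
    "subject_phenotype": "HPO",
    "collection_anatomy": "UBERON",
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for one synthetic submission."""

    seed: int = 0
    dcc: str = "EXAMPLE"
    n_files: int = 20
    n_biosamples: int = 10
    n_subjects: int = 5
    n_projects: int = 2
    n_collections: int = 3
    annotation_rate: dict = dc_field(default_factory=dict)
    vocab_size: int = 12
    dag_depth: int = 3
    dag_branching: int = 2
    defect: str | None = None

    def __post_init__(self):
        for key, rate in self.annotation_rate.items():
            if not 0.0 <= rate <= 1.0:
                raise C2M2Error(errors.BAD_CONFIG,
                                f"rate for {key!r} must be in [0, 1]")
        for n in (self.n_files, self.n_biosamples, self.n_subjects,
                  self.n_projects, self.n_collections):
            if n < 0:
                raise C2M2Error(errors.BAD_CONFIG, "counts must be >= 0")
        if self.defect is not None and self.defect not in INJECTABLE_CODES:
            raise C2M2Error(errors.BAD_CONFIG,
                            f"unknown defect code {self.defect!r}")
        if self.defect == errors.DUPLICATE_PK and self.n_subjects < 1:
            raise C2M2Error(errors.BAD_CONFIG,
                            "DUPLICATE_PK injection needs n_subjects >= 1")

    def rate(self, facet):
        return self.annotation_rate.get(facet, DEFAULT_RATES.get(facet, 0.0))

    @property
    def namespace(self):
        return f"https://ns.example.org/{self.dcc.lower()}"


def _rng(config, label):
    """One independent stream per artifact kind."""
    return random.Random(zlib.crc32(f"{config.seed}|{label}".encode()))


# ---------------------------------------------------------------------------
# Mini-ontologies.
# ---------------------------------------------------------------------------

def _term_id(vocabulary, index):
    if vocabulary == "Ensembl":
        return f"ENSG{index:011d}"
    if vocabulary == "UniProtKB":
        return f"P{index:05d}"
    prefix = sorted(VOCAB_PREFIXES[vocabulary])[0]
    return f"{prefix}:{index:07d}"


def generate_mini_ontology(vocabulary, config):
    """A small vocabulary: reference terms, an ``is_a`` DAG, and a slim.

    The DAG is a rooted tree of the configured depth and branching, widened
    with extra leaves until ``vocab_size`` terms exist; the slim is the set
    of depth-1 terms, so every non-root term has at least one slim image.
    The reference additionally carries one obsolete term (with
    ``replaced_by``) and one provisional term in the sidecar.  Accession
    vocabularies (Ensembl, UniProtKB) get a flat reference and no DAG.

    Returns ``(ref, provisional_ref, dag, slim)``; the last two are ``None``
    for flat vocabularies.
    """
    rng = _rng(config, f"ontology:{vocabulary}")
    size = max(config.vocab_size, config.dag_branching + 2)
    ref = VocabularyRef(vocabulary=vocabulary, version=f"synthetic-{config.seed}")

    def record(i, **kw):
        return TermRecord(
            id=_term_id(vocabulary, i),
            name=f"{vocabulary.lower()} term {i}",
            description=f"synthetic {vocabulary} concept number {i}",
            synonyms=(f"{vocabulary.lower()}-syn-{i}",
                      f"{vocabulary.lower()}-alt-{i}"),
            **kw)

    for i in range(size):
        ref.add(record(i))
    # One obsolete term pointing at a live replacement, one provisional term.
    ref.add(record(size, obsolete=True,
                   replaced_by=_term_id(vocabulary, rng.randrange(size))))
    provisional = VocabularyRef(vocabulary=vocabulary)
    provisional.add(TermRecord(
        id=_term_id(vocabulary, size + 1),
        name=f"{vocabulary.lower()} provisional term",
        description="synthetic term awaiting curation approval",
        provisional=True))

    if vocabulary in ("Ensembl", "UniProtKB"):
        return ref, provisional, None, None

    edges = []
    depth_of = {0: 0}
    frontier = [0]
    next_index = 1
    for depth in range(1, config.dag_depth + 1):
        new_frontier = []
        for parent in frontier:
            for _ in range(config.dag_branching):
                if next_index >= size:
                    break
                edges.append((_term_id(vocabulary, next_index),
                              _term_id(vocabulary, parent)))
                depth_of[next_index] = depth
                new_frontier.append(next_index)
                next_index += 1
        frontier = new_frontier or frontier
    while next_index < size:
        # widen with extra leaves under random non-root internal nodes
        parent = rng.choice([i for i, d in depth_of.items() if d >= 1] or [0])
        edges.append((_term_id(vocabulary, next_index),
                      _term_id(vocabulary, parent)))
        depth_of[next_index] = depth_of[parent] + 1
        next_index += 1

    dag = slim_mod.OntologyDag(
        vocabulary, edges=edges,
        nodes=[_term_id(vocabulary, i) for i in range(size)])
    slim_terms = frozenset(_term_id(vocabulary, i)
                           for i, d in depth_of.items() if d == 1)
    return ref, provisional, dag, slim_mod.SlimMap(vocabulary, slim_terms)


def generate_references(config):
    """Mini-ontologies for all supported vocabularies.

    Returns ``(refs, provisional, dags, slims)`` keyed by vocabulary.
    """
    refs, provisional, dags, slims = {}, {}, {}, {}
    for vocabulary in VOCABULARIES:
        ref, prov, dag, slim = generate_mini_ontology(vocabulary, config)
        refs[vocabulary] = ref
        provisional[vocabulary] = prov
        if dag is not None:
            dags[vocabulary] = dag
            slims[vocabulary] = slim
    return refs, provisional, dags, slims


def write_references(config, directory):
    """Write reference, provisional, DAG and slim files for all vocabularies."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    refs, provisional, dags, slims = generate_references(config)
    for vocabulary in VOCABULARIES:
        vocab.write_reference(refs[vocabulary],
                              directory / f"{vocabulary}.ref.tsv")
        vocab.write_provisional(provisional[vocabulary].terms.values(),
                                vocabulary, directory)
        if vocabulary in dags:
            dags[vocabulary].write(directory / f"{vocabulary}.dag.tsv")
            slims[vocabulary].write(directory / f"{vocabulary}.slim.tsv")
    return refs, provisional, dags, slims


def load_reference_dir(directory):
    """Read back everything :func:`write_references` wrote."""
    directory = Path(directory)
    refs, provisional = vocab.load_references(directory)
    dags, slims = {}, {}
    for vocabulary in VOCABULARIES:
        dag_path = directory / f"{vocabulary}.dag.tsv"
        if dag_path.exists():
            dags[vocabulary] = slim_mod.OntologyDag.read(dag_path, vocabulary)
            slims[vocabulary] = slim_mod.SlimMap.read(
                directory / f"{vocabulary}.slim.tsv")
    return refs, provisional, dags, slims


# ---------------------------------------------------------------------------
# Synthetic packages.
# ---------------------------------------------------------------------------

def minimal_package(registry=None, namespace="https://ns.example.org/minimal",
                    dcc="MINIMAL"):
    """The smallest package that validates: three records, all else stubs.

    One DCC contact record, one attribution project, one registered ID
    namespace — the strictly required minimum for a compliant submission.
    """
    registry = registry or build_registry()
    pkg = tsv.DataPackage.empty(registry)
    pkg.tables["id_namespace"].records.append({
        "id": namespace, "abbreviation": None,
        "name": f"{dcc} namespace", "description": None,
    })
    pkg.tables["project"].records.append({
        "id_namespace": namespace, "local_id": "ROOT",
        "persistent_id": None, "creation_time": None,
        "name": f"{dcc} attribution project",
        "abbreviation": None, "description": None,
    })
    pkg.tables["dcc"].records.append({
        "id": f"cfde_registry_dcc:{dcc.lower()}",
        "dcc_name": f"{dcc} Data Coordination Center",
        "dcc_abbreviation": dcc, "dcc_description": None,
        "contact_email": f"helpdesk@{dcc.lower()}.example.org",
        "contact_name": f"{dcc} Helpdesk", "dcc_url": None,
        "project_id_namespace": namespace, "project_local_id": "ROOT",
    })
    return pkg

_RESERVING_DEFECTS = frozenset({
    errors.FK_VIOLATION, errors.ORPHAN_ENTITY, errors.NAMESPACE_UNREGISTERED,
    errors.UNKNOWN_TERM, errors.WRONG_VOCABULARY,
})


def generate_package(config, registry=None, refs=None, provisional=None):
    """Build a deterministic synthetic submission with known ground truth.

    Returns ``(pkg, sidecar)``.  The sidecar records every planted
    annotation (facet -> local_id -> sorted terms), membership and linkage,
    and the exact connectivity percentages the catalog should report.  With
    ``defect=None`` the package validates cleanly by construction; defects
    are planted later, file-level, by :func:`inject_defect`.
    """
    registry = registry or build_registry()
    if refs is None:
        refs, provisional, _, _ = generate_references(config)
    pkg = tsv.DataPackage.empty(registry)
    ns = config.namespace

    # A record index reserved for row-targeted defect injection: it takes no
    # annotations or memberships, so tampering with it perturbs nothing else.
    reserved_file = (config.n_files - 1
                     if config.defect in _RESERVING_DEFECTS else None)
    if reserved_file is not None and config.n_files < 2:
        raise C2M2Error(errors.BAD_CONFIG,
                        f"defect {config.defect} needs n_files >= 2")

    pkg.tables["id_namespace"].records.append({
        "id": ns, "abbreviation": config.dcc.lower(),
        "name": f"{config.dcc} namespace",
        "description": f"synthetic namespace for DCC {config.dcc}",
    })

    n_projects = max(1, config.n_projects)
    project_ids = [f"PRJ{i:04d}" for i in range(n_projects)]
    for i, local in enumerate(project_ids):
        pkg.tables["project"].records.append({
            "id_namespace": ns, "local_id": local,
            "persistent_id": None, "creation_time": None,
            "name": f"{config.dcc} project {i}" if i else
                    f"{config.dcc} attribution project",
            "abbreviation": f"{config.dcc}-P{i}",
            "description": f"synthetic project {i} of DCC {config.dcc}",
        })
    for child in project_ids[1:]:
        pkg.tables["project_in_project"].records.append({
            "parent_project_id_namespace": ns,
            "parent_project_local_id": project_ids[0],
            "child_project_id_namespace": ns,
            "child_project_local_id": child,
        })

    pkg.tables["dcc"].records.append({
        "id": f"cfde_registry_dcc:{config.dcc.lower()}",
        "dcc_name": f"{config.dcc} Data Coordination Center",
        "dcc_abbreviation": config.dcc,
        "dcc_description": "synthetic DCC contact record",
        "contact_email": f"helpdesk@{config.dcc.lower()}.example.org",
        "contact_name": f"{config.dcc} Helpdesk",
        "dcc_url": f"https://{config.dcc.lower()}.example.org",
        "project_id_namespace": ns, "project_local_id": project_ids[0],
    })

    for gid, gname in (("cfde_subject_granularity:0", "single organism"),
                       ("cfde_subject_granularity:1", "cell line")):
        pkg.tables["subject_granularity"].records.append(
            {"id": gid, "name": gname, "description": None})
    for rid, rname in (("cfde_subject_role:0", "single organism"),
                       ("cfde_subject_role:1", "host")):
        pkg.tables["subject_role"].records.append(
            {"id": rid, "name": rname, "description": None})

    def project_for(i):
        return project_ids[i % n_projects]

    subject_ids = [f"SUB{i:04d}" for i in range(config.n_subjects)]
    for i, local in enumerate(subject_ids):
        pkg.tables["subject"].records.append({
            "id_namespace": ns, "local_id": local,
            "project_id_namespace": ns, "project_local_id": project_for(i),
            "persistent_id": None, "creation_time": None,
            "name": f"subject {i}", "description": None,
            "granularity": f"cfde_subject_granularity:{i % 2}",
        })

    biosample_ids = [f"BIO{i:04d}" for i in range(config.n_biosamples)]
    for i, local in enumerate(biosample_ids):
        pkg.tables["biosample"].records.append({
            "id_namespace": ns, "local_id": local,
            "project_id_namespace": ns, "project_local_id": project_for(i),
            "persistent_id": None, "creation_time": None,
            "name": f"biosample {i}", "description": None,
            "assay_type": None, "anatomy": None,
        })
        if subject_ids:
            pkg.tables["biosample_from_subject"].records.append({
                "biosample_id_namespace": ns, "biosample_local_id": local,
                "subject_id_namespace": ns,
                "subject_local_id": subject_ids[i % len(subject_ids)],
            })

    file_ids = [f"FIL{i:04d}" for i in range(config.n_files)]
    for i, local in enumerate(file_ids):
        pkg.tables["file"].records.append({
            "id_namespace": ns, "local_id": local,
            "project_id_namespace": ns, "project_local_id": project_for(i),
            "persistent_id": None, "creation_time": None,
            "filename": f"data_{i:04d}.dat", "size_in_bytes": str(1000 + i),
            "file_format": None, "compression_format": None,
            "data_type": None, "assay_type": None, "analysis_type": None,
            "mime_type": None,
        })

    collection_ids = [f"COL{i:04d}" for i in range(config.n_collections)]
    for i, local in enumerate(collection_ids):
        pkg.tables["collection"].records.append({
            "id_namespace": ns, "local_id": local,
            "persistent_id": None, "creation_time": None,
            "name": f"collection {i}", "abbreviation": f"C{i}",
            "description": f"synthetic collection {i}",
        })

    sidecar = {
        "dcc": config.dcc, "namespace": ns, "seed": config.seed,
        "counts": {"file": config.n_files, "biosample": config.n_biosamples,
                   "subject": config.n_subjects, "project": n_projects,
                   "collection": config.n_collections},
        "facets": {}, "memberships": {}, "links": {}, "rates": {},
    }

    # Collection membership: partition entities across collections
    # round-robin; the reserved record stays out.
    memberships = {"file": {}, "biosample": {}, "subject": {}}
    if collection_ids:
        for kind, ids, table in (
                ("file", file_ids, "file_in_collection"),
                ("biosample", biosample_ids, "biosample_in_collection"),
                ("subject", subject_ids, "subject_in_collection")):
            for i, local in enumerate(ids):
                if kind == "file" and reserved_file is not None \
                        and i == reserved_file:
                    continue
                coll = collection_ids[i % len(collection_ids)]
                pkg.tables[table].records.append({
                    f"{kind}_id_namespace": ns, f"{kind}_local_id": local,
                    "collection_id_namespace": ns,
                    "collection_local_id": coll,
                })
                memberships[kind][local] = [coll]
        for i, coll in enumerate(collection_ids):
            pkg.tables["collection_defined_by_project"].records.append({
                "collection_id_namespace": ns, "collection_local_id": coll,
                "project_id_namespace": ns,
                "project_local_id": project_for(i),
            })
    sidecar["memberships"] = memberships
    sidecar["links"]["biosample_from_subject"] = {
        local: subject_ids[i % len(subject_ids)]
        for i, local in enumerate(biosample_ids)} if subject_ids else {}

    def plant_population(kind, ids):
        if kind == "file" and reserved_file is not None:
            return ids[:reserved_file]
        return ids

    def pick(rng, ids, k):
        chosen = list(ids)
        rng.shuffle(chosen)
        return sorted(chosen[:k])

    ref_terms = {
        v: sorted(t for t, rec in refs[v].terms.items() if not rec.obsolete)
        for v in VOCABULARIES}

    entity_ids = {"file": file_ids, "biosample": biosample_ids,
                  "subject": subject_ids, "collection": collection_ids}

    # Entity CV fields: facet "entity.field".
    field_facets = [f for f in _FACET_VOCAB if "." in f]
    for facet in sorted(field_facets):
        entity, field_name = facet.split(".")
        ids = plant_population(entity, entity_ids[entity])
        rate = config.rate(facet)
        k = round(rate * len(ids))
        rng = _rng(config, f"facet:{facet}")
        chosen = pick(rng, ids, k)
        terms = ref_terms[_FACET_VOCAB[facet]]
        planted = {}
        index = {r["local_id"]: r for r in pkg.tables[entity].records}
        for local in chosen:
            term = terms[rng.randrange(len(terms))]
            index[local][field_name] = term
            planted[local] = [term]
        sidecar["facets"][facet] = planted
        sidecar["rates"][facet] = rate

    # CV association tables: facet = table name.
    assoc_facets = [f for f in _FACET_VOCAB if "." not in f]
    for facet in sorted(assoc_facets):
        entity = facet.split("_")[0]
        term_field = facet.split("_", 1)[1]
        if term_field == "phenotype":
            term_field = "phenotype"
        ids = plant_population(entity, entity_ids[entity])
        rate = config.rate(facet)
        k = round(rate * len(ids))
        rng = _rng(config, f"facet:{facet}")
        chosen = pick(rng, ids, k)
        terms = ref_terms[_FACET_VOCAB[facet]]
        planted = {}
        for local in chosen:
            term = terms[rng.randrange(len(terms))]
            pkg.tables[facet].records.append({
                f"{entity}_id_namespace": ns, f"{entity}_local_id": local,
                term_field: term,
            })
            planted[local] = [term]
        sidecar["facets"][facet] = planted
        sidecar["rates"][facet] = rate

    # file_describes_biosample linkage at its configured rate.
    if biosample_ids:
        ids = plant_population("file", file_ids)
        rate = config.rate("file_describes_biosample")
        k = round(rate * len(ids))
        rng = _rng(config, "link:file_describes_biosample")
        chosen = pick(rng, ids, k)
        linked = {}
        for local in chosen:
            target = biosample_ids[rng.randrange(len(biosample_ids))]
            pkg.tables["file_describes_biosample"].records.append({
                "file_id_namespace": ns, "file_local_id": local,
                "biosample_id_namespace": ns, "biosample_local_id": target,
            })
            linked[local] = target
        sidecar["links"]["file_describes_biosample"] = linked
        sidecar["rates"]["file_describes_biosample"] = rate

    vocab.build_term_tables(pkg, refs, provisional)
    sidecar["reserved_file"] = (file_ids[reserved_file]
                                if reserved_file is not None else None)
    # An EDAM term guaranteed never planted (obsolete terms are excluded from
    # the planting pool): the stray-term-table-row injection uses it.
    obsolete_edam = [t for t, rec in refs["EDAM"].terms.items() if rec.obsolete]
    sidecar["unused_edam_term"] = obsolete_edam[0] if obsolete_edam else None
    return pkg, sidecar


# ---------------------------------------------------------------------------
# Defect injection (file-level, applied to a written package directory).
# ---------------------------------------------------------------------------

def _edit_tsv(directory, table, fn):
    path = Path(directory) / f"{table}.tsv"
    lines = path.read_text(encoding="utf-8").split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    lines = fn(lines)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _edit_row(directory, table, local_id, fn, id_field="local_id"):
    def edit(lines):
        header = lines[0].split("\t")
        col = header.index(id_field)
        for i in range(1, len(lines)):
            cells = lines[i].split("\t")
            if cells[col] == local_id:
                lines[i] = "\t".join(fn(header, cells))
                return lines
        raise AssertionError(f"row {local_id} not found in {table}")
    _edit_tsv(directory, table, edit)


def inject_defect(directory, code, sidecar):
    """Tamper a written package so validation reports exactly ``code``.

    Each planted defect is constructed not to cascade: the edited record
    carries no associations, memberships or term usages (the generator
    reserves one for row-targeted codes), or the edited table has no
    dependents.
    """
    reserved = sidecar.get("reserved_file")

    def set_cell(field_name, value):
        def fn(header, cells):
            cells[header.index(field_name)] = value
            return cells
        _edit_row(directory, "file", reserved, fn)

    if code == errors.MISSING_TABLE:
        (Path(directory) / "collection_protein.tsv").unlink()
    elif code == errors.BAD_HEADER:
        def swap(lines):
            cols = lines[0].split("\t")
            cols[0], cols[1] = cols[1], cols[0]
            lines[0] = "\t".join(cols)
            return lines
        _edit_tsv(directory, "protein_gene", swap)
    elif code == errors.BAD_ROW:
        _edit_tsv(directory, "phenotype_disease",
                  lambda lines: lines + ["HP:0000001"])
    elif code == errors.MISSING_VALUE:
        def blank_name(lines):
            header = lines[0].split("\t")
            col = header.index("name")
            cells = lines[1].split("\t")
            cells[col] = ""
            lines[1] = "\t".join(cells)
            return lines
        _edit_tsv(directory, "project", blank_name)
    elif code == errors.DUPLICATE_PK:
        _edit_tsv(directory, "subject", lambda lines: lines + [lines[-1]])
    elif code == errors.FK_VIOLATION:
        set_cell("project_local_id", "NO_SUCH_PROJECT")
    elif code == errors.MISSING_REQUIRED_RECORD:
        _edit_tsv(directory, "dcc", lambda lines: lines[:1])
    elif code == errors.ORPHAN_ENTITY:
        set_cell("project_id_namespace", "")
        set_cell("project_local_id", "")
    elif code == errors.NAMESPACE_UNREGISTERED:
        set_cell("id_namespace", "https://unregistered.example.org/nowhere")
    elif code == errors.UNKNOWN_TERM:
        set_cell("data_type", "EDAM:9999999")
    elif code == errors.WRONG_VOCABULARY:
        set_cell("data_type", "DOID:9999999")
    elif code == errors.TERM_TABLE_MISMATCH:
        stray = sidecar["unused_edam_term"]
        def add_unused(lines):
            return lines + [f"{stray}\tstray term\tnever used\t"]
        _edit_tsv(directory, "edam", add_unused)
    else:
        raise C2M2Error(errors.BAD_CONFIG, f"cannot inject {code!r}")


def generate_package_dir(config, directory, registry=None, refs=None,
                         provisional=None):
    """Write a synthetic package (defect applied if configured) to disk.

    Returns the sidecar ground truth.
    """
    registry = registry or build_registry()
    pkg, sidecar = generate_package(config, registry, refs, provisional)
    tsv.write_package(pkg, directory)
    if config.defect is not None:
        inject_defect(directory, config.defect, sidecar)
    return sidecar


# ---------------------------------------------------------------------------
# The published five-program metadata comparison (key/value cells).
# ---------------------------------------------------------------------------

PROGRAMS = ("ExRNA", "GTEx", "GMKF", "HMP", "LINCS")


@dataclass(frozen=True)
class TableCell:
    panel: str      # "A" or "B"
    concept: str    # e.g. "Sample Type"
    program: str    # one of PROGRAMS
    kind: str       # "key" or "value"
    text: str       # printed cell content ("NA" where the portal has none)


_PANEL_A = {
    "Sample Type": {
        "keys": ["RNA Isolation Kit", "SMNABTCHT", "Analyte Type",
                 "Body Product", "Cell line"],
        "values": [["Serum and Plasma Kit (Quigen)"],
                   ["RNA isolation_PAXgene Blood RNA (Manual)"],
                   ["RNA"], ["blood cell"], ["THP1"]],
    },
    "Analysis Pipeline": {
        "keys": ["Profiling Assay", "SMAFRZE", "Experiment Strategy",
                 "Type", "Assay"],
        "values": [["small RNA-Seq"], ["RNASEQ"], ["RNA-Seq"],
                   ["16s_raw_seq_set", "16s_trimmed_seq_set",
                    "host_transcriptomics_raw_seq_set",
                    "microb_transcriptomics_raw_seq_set"],
                   ["RNA-seq"]],
    },
    "Organism": {
        "keys": ["Species", "NA", "NA", "NA", "Organism"],
        "values": [["Human"], ["NA"], ["NA"], ["NA"], ["human"]],
    },
}

# Panel B is a synthetic reconstruction: the published extraction reproduces
# panel A verbatim but only describes panel B in prose.  The recoverable
# facts are kept exact — HMP's "Supersite" key, GTEx's "SMTS"/"SMTSD" keys
# and "Whole blood" value, and the single CURIE-valued cell ENVO:02000020 —
# and the remaining cells are filled with plausible free text / NAs.
_PANEL_B = {
    "General Tissue": {
        "keys": ["Biofluid Name", "SMTS", "NA", "Supersite", "NA"],
        "values": [["Serum"], ["Blood"], ["NA"], ["blood"], ["NA"]],
    },
    "Specific Tissue": {
        "keys": ["NA", "SMTSD", "NA", "NA", "NA"],
        "values": [["NA"], ["Whole blood"], ["NA"], ["NA"], ["NA"]],
    },
    "Anatomical Part": {
        "keys": ["NA", "NA", "NA", "Body Site", "NA"],
        "values": [["NA"], ["NA"], ["NA"], ["ENVO:02000020"], ["NA"]],
    },
}


def table1_fixture():
    """The key/value cells of the five-program comparison table, both panels.

    Returns a list of :class:`TableCell`.  Panel A cells are carried exactly
    as printed; panel B is a labelled synthetic reconstruction (see module
    comment above).  "NA" cells are printed content and are included.
    """
    cells = []
    for panel, data in (("A", _PANEL_A), ("B", _PANEL_B)):
        for concept, row in data.items():
            for program, key in zip(PROGRAMS, row["keys"]):
                cells.append(TableCell(panel, concept, program, "key", key))
            for program, values in zip(PROGRAMS, row["values"]):
                for value in values:
                    cells.append(TableCell(panel, concept, program, "value",
                                           value))
    return cells


def table1_value_cells():
    """Just the value-cell texts, the input to the CURIE census."""
    return [c.text for c in table1_fixture() if c.kind == "value"]


def count_table1_curies():
    """How many value cells parse as CURIEs with registered prefixes."""
    return sum(1 for text in table1_value_cells()
               if vocab.detect_curie(text) is not None)
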