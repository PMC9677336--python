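"""Brute-force reference implementations used to cross-check the library.

Everything here is written as plain nested loops over raw table records,
independent of the indexes and graph routines in the package, so agreement
between the two routes is meaningful.
"""

import re

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

MEMBERSHIP = {"file": "file_in_collection",
              "biosample": "biosample_in_collection",
              "subject": "subject_in_collection"}


def key_of(record, prefix=""):
    return (record[f"{prefix}id_namespace"], record[f"{prefix}local_id"])


def facet_terms(pkg, entity, key, facet):
    source = FACETS[entity][facet]
    terms = set()
    if source[0] == "field":
        for record in pkg.tables[entity].records:
            if key_of(record) == key and record.get(source[1]) is not None:
                terms.add(record[source[1]])
    else:
        _, table, column = source
        for row in pkg.tables[table].records:
            if (row.get(f"{entity}_id_namespace"),
                    row.get(f"{entity}_local_id")) == key and \
                    row.get(column) is not None:
                terms.add(row[column])
    return terms


def all_terms(pkg, entity, key):
    out = set()
    for facet in FACETS[entity]:
        out |= facet_terms(pkg, entity, key, facet)
    return out


def collections_of(pkg, entity, key):
    out = set()
    table = MEMBERSHIP.get(entity)
    if table is None:
        return out
    for row in pkg.tables[table].records:
        if (row[f"{entity}_id_namespace"], row[f"{entity}_local_id"]) == key:
            out.add((row["collection_id_namespace"],
                     row["collection_local_id"]))
    return out


def linked_records(pkg, entity, key):
    """(entity, key) pairs directly linked via the describes/from tables."""
    out = set()
    pairs = (("biosample_from_subject", "biosample", "subject"),
             ("file_describes_biosample", "file", "biosample"),
             ("file_describes_subject", "file", "subject"))
    for table, left, right in pairs:
        for row in pkg.tables[table].records:
            lk = (row[f"{left}_id_namespace"], row[f"{left}_local_id"])
            rk = (row[f"{right}_id_namespace"], row[f"{right}_local_id"])
            if entity == left and lk == key:
                out.add((right, rk))
            if entity == right and rk == key:
                out.add((left, lk))
    return out


# -- slim rollup ------------------------------------------------------------

def ancestors_by_relaxation(edges, term):
    """Transitive closure over child->parent edges by repeated relaxation."""
    anc = set()
    changed = True
    while changed:
        changed = False
        for child, parent in edges:
            if (child == term or child in anc) and parent not in anc:
                anc.add(parent)
                changed = True
    anc.discard(term)
    return anc


def slim_image(edges, slim_terms, term):
    candidates = {s for s in slim_terms
                  if s == term or s in ancestors_by_relaxation(edges, term)}
    return sorted(
        s for s in candidates
        if not any(s in ancestors_by_relaxation(edges, other)
                   for other in candidates if other != s))


# -- search oracles ---------------------------------------------------------

def faceted(pkg, entity, filters, edges_by_vocab=None, slims_by_vocab=None,
            facet_vocab=None):
    """Surviving local_ids for a conjunction of include/exclude filters."""
    survivors = []
    for record in pkg.tables[entity].records:
        key = key_of(record)
        ok = True
        for f in filters:
            terms = facet_terms(pkg, entity, key, f.facet)
            if f.slim:
                vocabulary = facet_vocab[f.facet]
                edges = edges_by_vocab[vocabulary]
                slim_terms = slims_by_vocab[vocabulary]
                image = set()
                for t in terms:
                    mapped = slim_image(edges, slim_terms, t)
                    image.update(mapped if mapped else {"unclassified"})
                terms = image
            if f.include and not (terms & set(f.include)):
                ok = False
                break
            if terms & set(f.exclude):
                ok = False
                break
        if ok:
            survivors.append(record["local_id"])
    return sorted(survivors)


def _tokens(text):
    return {t for t in re.split(r"[^a-z0-9]+", text.lower()) if t}


def term_texts(pkg, term):
    texts = [term]
    for table in pkg.tables.values():
        if table.spec.kind != "term":
            continue
        for row in table.records:
            if row["id"] == term:
                texts.extend(filter(None, (row.get("name"),
                                           row.get("description"),
                                           row.get("synonyms"))))
    return texts


def record_tokens(pkg, entity, record):
    key = key_of(record)
    texts = []
    for term in all_terms(pkg, entity, key):
        texts.extend(term_texts(pkg, term))
    for f in ("name", "description", "abbreviation", "filename"):
        if record.get(f):
            texts.append(record[f])
    pns, plocal = record.get("project_id_namespace"), record.get(
        "project_local_id")
    for project in pkg.tables["project"].records:
        if key_of(project) == (pns, plocal):
            for f in ("name", "description", "abbreviation"):
                if project.get(f):
                    texts.append(project[f])
    for ckey in collections_of(pkg, entity, key):
        for coll in pkg.tables["collection"].records:
            if key_of(coll) == ckey:
                for f in ("name", "description", "abbreviation"):
                    if coll.get(f):
                        texts.append(coll[f])
        for term in all_terms(pkg, "collection", ckey):
            texts.extend(term_texts(pkg, term))
    for other_entity, other_key in linked_records(pkg, entity, key):
        for term in all_terms(pkg, other_entity, other_key):
            texts.extend(term_texts(pkg, term))
    out = set()
    for text in texts:
        out |= _tokens(text)
    return out


def keyword(pkg, entity, text):
    wanted = _tokens(text)
    return sorted(
        r["local_id"] for r in pkg.tables[entity].records
        if wanted <= record_tokens(pkg, entity, r))


def term_groups(pkg, curie):
    """local_ids per entity type associated with one term."""
    annotated = {key_of(c) for c in pkg.tables["collection"].records
                 if curie in all_terms(pkg, "collection", key_of(c))}
    groups = {}
    for entity in ("file", "biosample", "subject", "project", "collection"):
        hits = []
        for record in pkg.tables[entity].records:
            key = key_of(record)
            direct = curie in all_terms(pkg, entity, key)
            via = (entity == "collection" and key in annotated) or \
                bool(collections_of(pkg, entity, key) & annotated)
            if direct or via:
                hits.append(record["local_id"])
        groups[entity] = sorted(hits)
    return groups
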