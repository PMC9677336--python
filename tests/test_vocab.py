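"""CURIE detection, reference files, and the term-table builder."""

import pytest

from c2m2 import errors, fixtures, tsv, vocab
from c2m2.errors import C2M2Error
from c2m2.validate import validate_package
from c2m2.vocab import (TermRecord, VocabularyRef, build_term_tables,
                        collect_used_terms, detect_curie, term_table_name)


@pytest.mark.parametrize("value,expected", [
    ("ENVO:02000020", ("ENVO", "02000020")),
    ("UBERON:0000178", ("UBERON", "0000178")),
    ("NCBITaxon:9606", ("NCBITaxon", "9606")),
    ("Serum and Plasma Kit (Quigen)", None),       # free text
    ("RNA isolation_PAXgene Blood RNA (Manual)", None),
    ("SOMEPREFIX:123", None),                      # unregistered prefix
    ("envo:02000020", None),                       # case-sensitive prefix
    ("UBERON:", None),                             # empty local part
    ("ENSG00000123456", None),                     # accession, not a CURIE
    (None, None),
])
def test_curie_detection(value, expected):
    assert detect_curie(value) == expected


@pytest.mark.parametrize("vocabulary,good,bad", [
    ("Ensembl", "ENSG00000139618", "ENSG123"),
    ("UniProtKB", "P12345", "12345P"),
    ("UBERON", "UBERON:0000178", "DOID:1234"),
])
def test_term_id_vocabulary_routing(vocabulary, good, bad):
    assert vocab.term_id_matches_vocabulary(vocabulary, good)
    assert not vocab.term_id_matches_vocabulary(vocabulary, bad)


def test_reference_file_round_trip(tmp_path):
    ref = VocabularyRef("UBERON", version="v1")
    ref.add(TermRecord("UBERON:0000178", "blood",
                       description="the red fluid", synonyms=("vital fluid",)))
    ref.add(TermRecord("UBERON:0000001", "gone", obsolete=True,
                       replaced_by="UBERON:0000178"))
    path = tmp_path / "UBERON.ref.tsv"
    vocab.write_reference(ref, path)
    back = vocab.read_reference(path, "UBERON", version="v1")
    assert back.terms == ref.terms


def _one_biosample_package(registry, anatomy="UBERON:0000003"):
    pkg = fixtures.minimal_package(registry)
    ns = pkg.tables["id_namespace"].records[0]["id"]
    pkg.tables["biosample"].records.append({
        "id_namespace": ns, "local_id": "B1",
        "project_id_namespace": ns, "project_local_id": "ROOT",
        "persistent_id": None, "creation_time": None,
        "name": None, "description": None,
        "assay_type": None, "anatomy": anatomy,
    })
    return pkg


def test_collect_used_terms_routes_to_bound_vocabulary(registry):
    pkg = _one_biosample_package(registry, anatomy="UBERON:0000003")
    used = collect_used_terms(pkg, registry)
    assert used["UBERON"] == {"UBERON:0000003"}
    assert all(not terms for v, terms in used.items() if v != "UBERON")


def test_stub_package_uses_no_terms(registry):
    pkg = tsv.DataPackage.empty(registry)
    used = collect_used_terms(pkg, registry)
    assert all(not terms for terms in used.values())


def test_repeated_term_collected_once(registry, refs):
    pkg = _one_biosample_package(registry)
    ns = pkg.tables["id_namespace"].records[0]["id"]
    term = "UBERON:0000003"
    for i in range(5):
        pkg.tables["collection"].records.append({
            "id_namespace": ns, "local_id": f"C{i}", "persistent_id": None,
            "creation_time": None, "name": None, "abbreviation": None,
            "description": None})
        pkg.tables["collection_anatomy"].records.append({
            "collection_id_namespace": ns, "collection_local_id": f"C{i}",
            "anatomy": term})
    used = collect_used_terms(pkg, registry)
    assert used["UBERON"] == {term}


def test_term_tables_import_reference_descriptions(registry, refs,
                                                   provisional):
    pkg = _one_biosample_package(registry, anatomy="UBERON:0000003")
    ns = pkg.tables["id_namespace"].records[0]["id"]
    pkg.tables["collection"].records.append({
        "id_namespace": ns, "local_id": "C1", "persistent_id": None,
        "creation_time": None, "name": None, "abbreviation": None,
        "description": None})
    pkg.tables["collection_anatomy"].records.append({
        "collection_id_namespace": ns, "collection_local_id": "C1",
        "anatomy": "UBERON:0000005"})
    build_term_tables(pkg, refs, provisional)
    rows = pkg.tables[term_table_name("UBERON")].records
    assert [r["id"] for r in rows] == ["UBERON:0000003", "UBERON:0000005"]
    for row in rows:
        assert row["name"] == refs["UBERON"].terms[row["id"]].name
        assert row["description"] == refs["UBERON"].terms[row["id"]].description

    # all other vocabularies stay header-only
    for vocabulary in vocab.VOCABULARIES:
        if vocabulary != "UBERON":
            assert pkg.tables[term_table_name(vocabulary)].records == []


def test_term_table_build_is_idempotent(registry, refs, provisional):
    pkg = _one_biosample_package(registry)
    build_term_tables(pkg, refs, provisional)
    snapshot = {v: list(pkg.tables[term_table_name(v)].records)
                for v in vocab.VOCABULARIES}
    build_term_tables(pkg, refs, provisional)
    assert snapshot == {v: list(pkg.tables[term_table_name(v)].records)
                        for v in vocab.VOCABULARIES}


def test_provisional_term_is_accepted_and_flagged(registry, refs,
                                                  provisional):
    prov_id = next(iter(provisional["UBERON"].terms))
    pkg = _one_biosample_package(registry, anatomy=prov_id)
    build_term_tables(pkg, refs, provisional)
    rows = pkg.tables[term_table_name("UBERON")].records
    assert [r["id"] for r in rows] == [prov_id]
    resolved = vocab.term_records_in_package(pkg, refs, provisional)
    assert resolved["UBERON"][prov_id].provisional is True


def test_unknown_term_is_refused(registry, refs, provisional):
    pkg = _one_biosample_package(registry, anatomy="UBERON:9999999")
    with pytest.raises(C2M2Error) as exc:
        build_term_tables(pkg, refs, provisional)
    assert exc.value.code == errors.UNKNOWN_TERM


def test_wrong_vocabulary_prefix_is_flagged(registry):
    pkg = _one_biosample_package(registry, anatomy="DOID:0000123")
    issues = []
    used = collect_used_terms(pkg, registry, issues=issues)
    assert [i.code for i in issues] == [errors.WRONG_VOCABULARY]
    assert not used["UBERON"] and not used["DiseaseOntology"]


def test_obsolete_term_keeps_validating(registry, refs, provisional):
    """A dataset citing a term later obsoleted must stay valid."""
    obsolete_id = next(t for t, r in refs["UBERON"].terms.items() if r.obsolete)
    pkg = _one_biosample_package(registry, anatomy=obsolete_id)
    build_term_tables(pkg, refs, provisional)
    report = validate_package(pkg, registry, refs, provisional)
    assert report.valid
    resolved = vocab.term_records_in_package(pkg, refs, provisional)
    assert resolved["UBERON"][obsolete_id].obsolete is True
    assert resolved["UBERON"][obsolete_id].replaced_by in refs["UBERON"].terms
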