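"""Ingest/release lifecycle, the three search modes, and statistics."""

import pytest

import _oracles
from c2m2 import catalog, errors, fixtures, tsv
from c2m2.catalog import (CatalogStore, FacetFilter, browse_terms,
                          compare_submissions, query_by_term, query_faceted,
                          query_keyword, summary_stats)
from c2m2.errors import C2M2Error
from c2m2.slim import map_to_slim
from c2m2.vocab import TermRecord, VocabularyRef, build_term_tables

ASPIRIN = "PUBCHEM:0002244"


def _package_dir(tmp_path, registry, refs, provisional, **kw):
    config = fixtures.GeneratorConfig(**kw)
    directory = tmp_path / f"pkg_{kw.get('dcc', 'X')}_{kw.get('seed', 0)}"
    fixtures.generate_package_dir(config, directory, registry, refs,
                                  provisional)
    return directory


def _released_store(registry, refs, provisional, tmp_path, seed=30,
                    dcc="AAA", **kw):
    store = CatalogStore(registry)
    directory = _package_dir(tmp_path, registry, refs, provisional,
                             seed=seed, dcc=dcc, **kw)
    sub = store.ingest(dcc, directory, refs, provisional)
    store.review(sub)
    store.approve(sub)
    return store, store.build_release(), sub


# -- lifecycle --------------------------------------------------------------

def test_ingest_assigns_sequence_and_uploaded_status(registry, refs,
                                                     provisional, tmp_path):
    store = CatalogStore(registry)
    directory = _package_dir(tmp_path, registry, refs, provisional, seed=31)
    sub = store.ingest("AAA", directory, refs, provisional)
    assert (sub.sequence, sub.status) == (1, "uploaded")


def test_invalid_package_is_rejected_with_report(registry, refs, provisional,
                                                 tmp_path):
    store = CatalogStore(registry)
    directory = _package_dir(tmp_path, registry, refs, provisional, seed=32,
                             defect=errors.FK_VIOLATION)
    sub = store.ingest("AAA", directory, refs, provisional)
    assert sub.status == "rejected"
    assert errors.FK_VIOLATION in sub.report.codes()
    assert sub in store.submissions  # retained despite rejection


def test_successive_ingests_are_all_retained(registry, refs, provisional,
                                             tmp_path):
    store = CatalogStore(registry)
    for seed in (33, 34):
        directory = _package_dir(tmp_path, registry, refs, provisional,
                                 seed=seed)
        store.ingest("AAA", directory, refs, provisional)
    assert [s.sequence for s in store.for_dcc("AAA")] == [1, 2]


def test_status_transitions_are_forward_only(registry, refs, provisional,
                                             tmp_path):
    store = CatalogStore(registry)
    directory = _package_dir(tmp_path, registry, refs, provisional, seed=35)
    sub = store.ingest("AAA", directory, refs, provisional)
    with pytest.raises(C2M2Error):
        store.approve(sub)          # cannot skip review
    store.review(sub)
    with pytest.raises(C2M2Error):
        store.review(sub)           # cannot repeat
    store.approve(sub)
    with pytest.raises(C2M2Error):
        store.reject(sub)           # cannot reject after approval


def test_release_replaces_wholesale_and_retains_absent_dccs(registry, refs,
                                                            provisional,
                                                            tmp_path):
    store = CatalogStore(registry)
    dir_a1 = _package_dir(tmp_path, registry, refs, provisional, seed=36,
                          dcc="AAA", n_files=5)
    dir_a2 = _package_dir(tmp_path, registry, refs, provisional, seed=37,
                          dcc="AAA", n_files=9)
    dir_b1 = _package_dir(tmp_path, registry, refs, provisional, seed=38,
                          dcc="BBB", n_files=3)

    a1 = store.ingest("AAA", dir_a1, refs, provisional)
    b1 = store.ingest("BBB", dir_b1, refs, provisional)
    for sub in (a1, b1):
        store.review(sub)
        store.approve(sub)
    view1 = store.build_release()
    assert {dcc: s.id for dcc, s in view1.submissions.items()} == \
        {"AAA": "AAA:1", "BBB": "BBB:1"}

    a2 = store.ingest("AAA", dir_a2, refs, provisional)
    store.review(a2)
    store.approve(a2)
    view2 = store.build_release()
    # newest approved replaces AAA completely; BBB untouched
    assert view2.submissions["AAA"] is a2
    assert view2.submissions["BBB"] is b1
    assert len(query_faceted(view2, "file", [])) == 9 + 3

    # idempotent rebuild with no new approvals
    view3 = store.build_release()
    assert view3.submissions == view2.submissions


def test_merged_release_has_no_key_collisions(registry, refs, provisional,
                                              tmp_path):
    store = CatalogStore(registry)
    for seed, dcc in ((40, "AAA"), (41, "BBB")):
        directory = _package_dir(tmp_path, registry, refs, provisional,
                                 seed=seed, dcc=dcc)
        sub = store.ingest(dcc, directory, refs, provisional)
        store.review(sub)
        store.approve(sub)
    view = store.build_release()
    keys = view.global_keys()
    assert len(keys) == len(set(keys))


def test_store_round_trips_through_sqlite(registry, refs, provisional,
                                          tmp_path):
    store, view, sub = _released_store(registry, refs, provisional, tmp_path,
                                       seed=42)
    db = tmp_path / "catalog.db"
    store.save(db)
    loaded = CatalogStore.load(db, registry)
    assert [s.id for s in loaded.submissions] == [s.id for s in
                                                  store.submissions]
    assert loaded.submissions[0].package == store.submissions[0].package
    assert list(loaded.public_view.submissions) == ["AAA"]


# -- faceted search ---------------------------------------------------------

def test_empty_filter_list_returns_every_record(registry, refs, provisional,
                                                tmp_path):
    _, view, sub = _released_store(registry, refs, provisional, tmp_path,
                                   seed=43)
    result = query_faceted(view, "file", [])
    assert len(result) == len(sub.package.tables["file"].records)


def test_overlapping_include_exclude_is_refused():
    with pytest.raises(C2M2Error) as exc:
        FacetFilter("file_format", include={"X"}, exclude={"X"})
    assert exc.value.code == errors.BAD_FACET


def test_unknown_facet_is_refused(registry, refs, provisional, tmp_path):
    _, view, _ = _released_store(registry, refs, provisional, tmp_path,
                                 seed=44)
    with pytest.raises(C2M2Error) as exc:
        query_faceted(view, "file", [FacetFilter("anatomy", include={"X"})])
    assert exc.value.code == errors.BAD_FACET


def test_conjunctive_filters_match_bruteforce_scan(registry, refs,
                                                   provisional, tmp_path):
    _, view, sub = _released_store(registry, refs, provisional, tmp_path,
                                   seed=4, n_files=40)
    pkg = sub.package
    sidecar_terms = sorted({t for r in pkg.tables["file"].records
                            for t in [r.get("file_format")] if t})
    filters = [
        FacetFilter("file_format", include=set(sidecar_terms[:2])),
        FacetFilter("assay_type", exclude={"OBI:0000001"}),
    ]
    result = query_faceted(view, "file", filters)
    assert result.local_ids() == _oracles.faceted(pkg, "file", filters)


def test_facet_counts_sum_to_result_size_for_full_coverage_facet(
        registry, refs, provisional, tmp_path):
    _, view, _ = _released_store(
        registry, refs, provisional, tmp_path, seed=45,
        annotation_rate={"file.file_format": 1.0})
    result = query_faceted(view, "file", [])
    assert sum(result.facet_counts["file_format"].values()) == len(result)


def test_slim_facet_unions_specific_terms(registry, refs, provisional, dags,
                                          slims, tmp_path):
    dag, slim = dags["UBERON"], slims["UBERON"]
    by_slim = {}
    for node in dag.nodes:
        for s in map_to_slim(dag, slim, node):
            by_slim.setdefault(s, []).append(node)
    slim_term, specific = next((s, nodes) for s, nodes in by_slim.items()
                               if len(nodes) >= 3)

    pkg = fixtures.minimal_package(registry)
    ns = pkg.tables["id_namespace"].records[0]["id"]
    for i, term in enumerate(specific[:3]):
        pkg.tables["biosample"].records.append({
            "id_namespace": ns, "local_id": f"B{i}",
            "project_id_namespace": ns, "project_local_id": "ROOT",
            "persistent_id": None, "creation_time": None, "name": None,
            "description": None, "assay_type": None, "anatomy": term})
    build_term_tables(pkg, refs, None)

    store = CatalogStore(registry)
    sub = store.ingest("AAA", pkg, refs)
    store.review(sub)
    store.approve(sub)
    view = store.build_release()
    result = query_faceted(
        view, "biosample", [FacetFilter("anatomy", include={slim_term},
                                        slim=True)],
        dags=dags, slims=slims)
    # recall preservation: every record annotated with a specific term is
    # retrieved when searching on its slim ancestor
    assert result.local_ids() == ["B0", "B1", "B2"]


# -- keyword search ---------------------------------------------------------

def _aspirin_fixture(registry):
    """One biosample per retrieval path for the keyword 'aspirin'."""
    refs = {"PubChem": VocabularyRef("PubChem")}
    refs["PubChem"].add(TermRecord(
        ASPIRIN, "aspirin", description="acetylsalicylic acid, an analgesic",
        synonyms=("acetosal",)))
    pkg = fixtures.minimal_package(registry)
    ns = pkg.tables["id_namespace"].records[0]["id"]

    def biosample(local, project="ROOT"):
        pkg.tables["biosample"].records.append({
            "id_namespace": ns, "local_id": local,
            "project_id_namespace": ns, "project_local_id": project,
            "persistent_id": None, "creation_time": None, "name": None,
            "description": None, "assay_type": None, "anatomy": None})

    # path 1: membership in a collection annotated with the aspirin term
    pkg.tables["collection"].records.append({
        "id_namespace": ns, "local_id": "COLA", "persistent_id": None,
        "creation_time": None, "name": "trial samples",
        "abbreviation": None, "description": None})
    pkg.tables["collection_substance"].records.append({
        "collection_id_namespace": ns, "collection_local_id": "COLA",
        "substance": ASPIRIN})
    biosample("B1")
    pkg.tables["biosample_in_collection"].records.append({
        "biosample_id_namespace": ns, "biosample_local_id": "B1",
        "collection_id_namespace": ns, "collection_local_id": "COLA"})

    # path 2: project whose name carries the word
    pkg.tables["project"].records.append({
        "id_namespace": ns, "local_id": "PASP", "persistent_id": None,
        "creation_time": None,
        "name": "Aspirin Metabolomics in Colorectal Cancer Prevention",
        "abbreviation": None, "description": None})
    biosample("B2", project="PASP")

    # path 3: derived from a subject administered the substance
    pkg.tables["subject"].records.append({
        "id_namespace": ns, "local_id": "S1",
        "project_id_namespace": ns, "project_local_id": "ROOT",
        "persistent_id": None, "creation_time": None, "name": None,
        "description": None, "granularity": None})
    pkg.tables["subject_substance"].records.append({
        "subject_id_namespace": ns, "subject_local_id": "S1",
        "substance": ASPIRIN})
    biosample("B3")
    pkg.tables["biosample_from_subject"].records.append({
        "biosample_id_namespace": ns, "biosample_local_id": "B3",
        "subject_id_namespace": ns, "subject_local_id": "S1"})

    biosample("B4")  # control: no aspirin connection
    build_term_tables(pkg, refs, None)
    return pkg, refs


def _view_for(registry, pkg, refs):
    store = CatalogStore(registry)
    sub = store.ingest("AAA", pkg, refs)
    store.review(sub)
    store.approve(sub)
    return store.build_release()


def test_keyword_reaches_all_three_aspirin_paths(registry):
    pkg, refs = _aspirin_fixture(registry)
    view = _view_for(registry, pkg, refs)
    result = query_keyword(view, "biosample", "aspirin")
    assert result.local_ids() == ["B1", "B2", "B3"]
    assert result.local_ids() == _oracles.keyword(pkg, "biosample", "aspirin")


def test_keyword_matches_synonyms_only_too(registry):
    pkg, refs = _aspirin_fixture(registry)
    view = _view_for(registry, pkg, refs)
    # "acetosal" appears only as a term synonym; B2 (project-name path) is
    # not attached to the term itself and must not match
    assert query_keyword(view, "biosample", "acetosal").local_ids() == \
        ["B1", "B3"]


def test_keyword_matching_nothing_is_empty(registry):
    pkg, refs = _aspirin_fixture(registry)
    view = _view_for(registry, pkg, refs)
    assert len(query_keyword(view, "biosample", "xylophone")) == 0


# -- term-centric search ----------------------------------------------------

def test_term_query_groups_by_entity_type(registry):
    pkg, refs = _aspirin_fixture(registry)
    ns = pkg.tables["id_namespace"].records[0]["id"]
    # a second direct biosample user of the term
    pkg.tables["biosample_substance"].records.append({
        "biosample_id_namespace": ns, "biosample_local_id": "B4",
        "substance": ASPIRIN})
    build_term_tables(pkg, refs, None)
    view = _view_for(registry, pkg, refs)
    groups = query_by_term(view, ASPIRIN)
    got = {entity: sorted(r["local_id"] for _, r in records)
           for entity, records in groups.items() if records}
    oracle = {e: ids for e, ids in _oracles.term_groups(pkg, ASPIRIN).items()
              if ids}
    assert got == oracle
    assert got["collection"] == ["COLA"]
    assert "B4" in got["biosample"] and "B1" in got["biosample"]


def test_unknown_term_query_is_refused(registry):
    pkg, refs = _aspirin_fixture(registry)
    view = _view_for(registry, pkg, refs)
    with pytest.raises(C2M2Error) as exc:
        query_by_term(view, "PUBCHEM:9999999")
    assert exc.value.code == errors.UNKNOWN_TERM


def test_term_browse_then_select_reproduces_term_query(registry):
    pkg, refs = _aspirin_fixture(registry)
    view = _view_for(registry, pkg, refs)
    hits = browse_terms(view, "analgesic")
    assert hits == [ASPIRIN]
    groups = query_by_term(view, hits[0])
    assert any(groups.values())


def test_term_listed_but_unused_yields_empty_groups(registry):
    pkg = fixtures.minimal_package(registry)
    # hand-plant a term-table row without any usage; build the view directly
    # (such a package is not submittable — the term table is out of sync)
    pkg.tables["pub_chem"].records.append(
        {"id": ASPIRIN, "name": "aspirin", "description": None,
         "synonyms": None})
    sub = catalog.Submission(dcc="AAA", sequence=1, status="public",
                             package=pkg)
    view = catalog.PublicView({"AAA": sub})
    groups = query_by_term(view, ASPIRIN)
    assert all(not records for records in groups.values())


# -- statistics -------------------------------------------------------------

def test_connectivity_is_zero_without_substance_links(registry, refs,
                                                      provisional):
    config = fixtures.GeneratorConfig(
        seed=7, n_biosamples=50,
        annotation_rate={"biosample_substance": 0.0})
    pkg, _ = fixtures.generate_package(config, registry, refs, provisional)
    stats = summary_stats(pkg)
    stat = stats.connectivity[("biosample", "substance")]
    assert (stat.percent, stat.empty) == (0.0, False)


def test_full_annotation_gives_complete_coverage(registry, refs, provisional):
    config = fixtures.GeneratorConfig(
        seed=46, annotation_rate={"file.data_type": 1.0})
    pkg, _ = fixtures.generate_package(config, registry, refs, provisional)
    stats = summary_stats(pkg)
    assert stats.connectivity[("file", "data_type")].percent == 100.0


def test_planted_rate_yields_exact_percentage(registry, refs, provisional):
    config = fixtures.GeneratorConfig(
        seed=5, n_files=200, annotation_rate={"file.data_type": 0.5})
    pkg, _ = fixtures.generate_package(config, registry, refs, provisional)
    stats = summary_stats(pkg)
    assert stats.connectivity[("file", "data_type")].percent == 50.0


def test_empty_entity_is_flagged_not_divided(registry, refs, provisional):
    config = fixtures.GeneratorConfig(seed=47, n_biosamples=0, n_files=2,
                                      n_subjects=1)
    pkg, _ = fixtures.generate_package(config, registry, refs, provisional)
    stats = summary_stats(pkg)
    stat = stats.connectivity[("biosample", "subject")]
    assert (stat.percent, stat.empty) == (0.0, True)


def test_stats_match_sidecar_ground_truth(registry, refs, provisional):
    config = fixtures.GeneratorConfig(seed=48)
    pkg, sidecar = fixtures.generate_package(config, registry, refs,
                                             provisional)
    stats = summary_stats(pkg)
    for facet in ("biosample_substance", "subject_disease"):
        entity, category = facet.split("_", 1)
        expected = 100.0 * len(sidecar["facets"][facet]) / \
            sidecar["counts"][entity]
        assert stats.connectivity[(entity, category)].percent == \
            pytest.approx(expected)


# -- submission comparison --------------------------------------------------

def test_identical_submissions_have_zero_deltas(registry, refs, provisional,
                                                tmp_path):
    store = CatalogStore(registry)
    directory = _package_dir(tmp_path, registry, refs, provisional, seed=49)
    a = store.ingest("AAA", directory, refs, provisional)
    b = store.ingest("AAA", directory, refs, provisional)
    delta = compare_submissions(a, b)
    assert all(v == 0 for v in delta.table_deltas.values())
    assert all(v == 0 for v in delta.connectivity_deltas.values())


def test_added_files_show_as_positive_delta(registry, refs, provisional,
                                            tmp_path):
    store = CatalogStore(registry)
    d1 = _package_dir(tmp_path, registry, refs, provisional, seed=50,
                      n_files=10)
    d2 = _package_dir(tmp_path, registry, refs, provisional, seed=51,
                      n_files=20)
    a = store.ingest("AAA", d1, refs, provisional)
    b = store.ingest("AAA", d2, refs, provisional)
    assert compare_submissions(a, b).table_deltas["file"] == 10


def test_replicate_merge_shrinks_biosamples_not_files(registry, refs,
                                                      provisional, tmp_path):
    """Re-modelling replicates as one biosample: biosample count drops while
    the file inventory is preserved."""
    store = CatalogStore(registry)
    d1 = _package_dir(tmp_path, registry, refs, provisional, seed=52,
                      n_files=12, n_biosamples=9)
    d2 = _package_dir(tmp_path, registry, refs, provisional, seed=53,
                      n_files=12, n_biosamples=3)
    a = store.ingest("AAA", d1, refs, provisional)
    b = store.ingest("AAA", d2, refs, provisional)
    delta = compare_submissions(a, b)
    assert delta.table_deltas["biosample"] < 0
    assert delta.table_deltas["file"] >= 0


def test_cross_dcc_comparison_is_refused(registry, refs, provisional,
                                         tmp_path):
    store = CatalogStore(registry)
    d1 = _package_dir(tmp_path, registry, refs, provisional, seed=54,
                      dcc="AAA")
    d2 = _package_dir(tmp_path, registry, refs, provisional, seed=55,
                      dcc="BBB")
    a = store.ingest("AAA", d1, refs, provisional)
    b = store.ingest("BBB", d2, refs, provisional)
    with pytest.raises(C2M2Error) as exc:
        compare_submissions(a, b)
    assert exc.value.code == errors.BAD_COMPARISON
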