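"""Baseline/enriched network construction, GCF assignment, categorisation,
profile selection and hull overlays."""

import logging

import numpy as np
import pytest

import netenrich as ne
from netenrich.diversity import ModelDiversity
from netenrich.errors import UsageError, ValidationError
from netenrich.network import summarize_gcfs


class UnionFind:
    """Independent component oracle."""

    def __init__(self):
        self.parent = {}

    def add(self, x):
        self.parent.setdefault(x, x)

    def find(self, x):
        while self.parent[x] != x:
            x = self.parent[x]
        return x

    def union(self, a, b):
        self.add(a)
        self.add(b)
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra

    def partition(self):
        groups = {}
        for x in self.parent:
            groups.setdefault(self.find(x), set()).add(x)
        return set(map(frozenset, groups.values()))


def bgc(i, genome="g1", cls="NRPS"):
    return ne.BGCRecord(f"BGC:{i}", genome, cls, False)


def gcf_partition(assignments):
    groups = {}
    for a in assignments:
        groups.setdefault(a.gcf_id, set()).add(a.bgc_id)
    return set(map(frozenset, groups.values()))


# --- build_baseline -------------------------------------------------------

def test_threshold_splits_components():
    records = [bgc("A"), bgc("B"), bgc("C")]
    edges = [ne.SimilarityEdge("BGC:A", "BGC:B", 0.2),
             ne.SimilarityEdge("BGC:B", "BGC:C", 0.6)]
    g = ne.build_baseline(edges, records, cutoff=0.3)
    parts = gcf_partition(ne.baseline_gcfs(g))
    assert parts == {frozenset({"BGC:A", "BGC:B"}), frozenset({"BGC:C"})}


def test_no_edges_gives_all_singletons():
    records = [bgc(i) for i in range(5)]
    g = ne.build_baseline([], records, cutoff=0.3)
    assignments = ne.baseline_gcfs(g)
    assert summarize_gcfs(assignments)["n_components"] == 5
    assert all(a.is_singleton for a in assignments)


def test_cutoff_boundary_edge_retained():
    records = [bgc("A"), bgc("B")]
    g = ne.build_baseline([ne.SimilarityEdge("BGC:A", "BGC:B", 0.3)], records, 0.3)
    assert g.has_edge("BGC:A", "BGC:B")  # <= semantics


def test_unknown_endpoint_lists_offenders():
    with pytest.raises(ValidationError, match="BGC:ghost"):
        ne.build_baseline([ne.SimilarityEdge("BGC:A", "BGC:ghost", 0.1)],
                          [bgc("A")], 0.3)


def test_invalid_cutoff_is_usage_error():
    with pytest.raises(UsageError):
        ne.build_baseline([], [bgc("A")], cutoff=0.0)


def test_mibig_member_coclusters_as_known():
    records = [bgc("A"), bgc("B")]
    edges = [ne.SimilarityEdge("BGC:A", "MIBIG:BGC0000001", 0.1)]
    g = ne.build_baseline(edges, records, 0.3, {"MIBIG:BGC0000001"})
    assignments = ne.baseline_gcfs(g)
    by_id = {a.bgc_id: a for a in assignments}
    assert by_id["BGC:A"].known_status == "known"
    assert not by_id["BGC:A"].is_singleton  # attached to a reference node
    assert by_id["BGC:B"].known_status == "unknown"


def test_baseline_gcfs_rejects_enriched_graph():
    g = ne.build_baseline([], [bgc("A")], 0.3)
    eg = ne.enrich(g, arts=[ne.ArtsHit("BGC:A", "ARTS:p", "core_model")])
    with pytest.raises(UsageError):
        ne.baseline_gcfs(eg)


# --- filter_models --------------------------------------------------------

def _div(model_id, share, h=1.0):
    return ModelDiversity(model_id, h, "X", share, 5, 100)


def test_filter_low_top_share_removed():
    (dec,) = ne.filter_models([_div("BIGFAM:m", 0.25)])
    assert dec.removed and dec.reason == "low_top_genus"


def test_filter_pure_model_kept():
    (dec,) = ne.filter_models([_div("BIGFAM:m", 1.0)])
    assert not dec.removed and dec.reason == "kept"


def test_filter_max_shannon_optional():
    divs = [_div("BIGFAM:a", 0.6, h=3.0), _div("BIGFAM:b", 0.6, h=1.0)]
    decs = {d.model_id: d for d in ne.filter_models(divs, max_shannon=2.0)}
    assert decs["BIGFAM:a"].removed and decs["BIGFAM:a"].reason == "high_shannon"
    assert not decs["BIGFAM:b"].removed


def test_filter_matches_brute_force_predicate():
    rng = np.random.default_rng(0)
    divs = [_div(f"BIGFAM:{i}", rng.uniform(0, 1), rng.uniform(0, 4))
            for i in range(50)]
    for min_share in (0.1, 0.3, 0.6):
        for max_h in (None, 2.0):
            decisions = ne.filter_models(divs, min_share, max_h)
            expected_removed = {
                d.model_id
                for d in divs
                if d.top_genus_share < min_share
                or (max_h is not None and d.shannon_h > max_h)
            }
            assert {d.model_id for d in decisions if d.removed} == expected_removed
            assert all((d.reason == "kept") != d.removed for d in decisions)


# --- enrich / enriched_gcfs ----------------------------------------------

def _two_family_graph():
    records = [bgc("A1"), bgc("A2"), bgc("B1"), bgc("B2")]
    edges = [ne.SimilarityEdge("BGC:A1", "BGC:A2", 0.1),
             ne.SimilarityEdge("BGC:B1", "BGC:B2", 0.1)]
    return ne.build_baseline(edges, records, 0.3)


def test_kcb_below_threshold_adds_no_edge():
    g = _two_family_graph()
    eg = ne.enrich(g, kcb=[ne.KnownClusterHit("BGC:A1", "MIBIG:BGC0000001", 79.9)])
    assert "MIBIG:BGC0000001" not in eg


def test_kcb_at_threshold_is_inclusive():
    g = _two_family_graph()
    eg = ne.enrich(g, kcb=[ne.KnownClusterHit("BGC:A1", "MIBIG:BGC0000001", 80.0)])
    assert eg.has_edge("BGC:A1", "MIBIG:BGC0000001")


def test_shared_mibig_hit_merges_components():
    g = _two_family_graph()
    kcb = [ne.KnownClusterHit("BGC:A1", "MIBIG:BGC0000001", 92.0),
           ne.KnownClusterHit("BGC:B1", "MIBIG:BGC0000001", 88.0)]
    eg = ne.enrich(g, kcb=kcb)
    assignments = ne.enriched_gcfs(eg)
    assert summarize_gcfs(assignments)["n_components"] == 1
    assert all(a.known_status == "known" for a in assignments)
    # union-find oracle over the same evidence
    uf = UnionFind()
    for n in ("BGC:A1", "BGC:A2", "BGC:B1", "BGC:B2"):
        uf.add(n)
    uf.union("BGC:A1", "BGC:A2")
    uf.union("BGC:B1", "BGC:B2")
    uf.union("BGC:A1", "MIBIG:BGC0000001")
    uf.union("BGC:B1", "MIBIG:BGC0000001")
    oracle = {frozenset(p - {"MIBIG:BGC0000001"}) for p in uf.partition()}
    assert gcf_partition(assignments) == oracle


def test_removed_model_adds_no_node_or_edge():
    g = _two_family_graph()
    decisions = [ne.ModelFilterDecision("BIGFAM:bad", True, "low_top_genus")]
    eg = ne.enrich(g, bigfam=[ne.BigfamMembership("BGC:A1", "BIGFAM:bad")],
                   model_filter=decisions)
    assert "BIGFAM:bad" not in eg


def test_kept_model_merges_but_does_not_mark_known():
    g = _two_family_graph()
    members = [ne.BigfamMembership("BGC:A1", "BIGFAM:m"),
               ne.BigfamMembership("BGC:B1", "BIGFAM:m")]
    eg = ne.enrich(g, bigfam=members)
    assignments = ne.enriched_gcfs(eg)
    assert summarize_gcfs(assignments)["n_components"] == 1
    assert all(a.known_status == "unknown" for a in assignments)
    assert all(a.linked_models == frozenset({"BIGFAM:m"}) for a in assignments)


def test_best_hit_only_keeps_first_membership(caplog):
    g = _two_family_graph()
    members = [ne.BigfamMembership("BGC:A1", "BIGFAM:m1"),
               ne.BigfamMembership("BGC:A1", "BIGFAM:m2")]
    with caplog.at_level(logging.WARNING):
        eg = ne.enrich(g, bigfam=members)
    assert eg.has_edge("BGC:A1", "BIGFAM:m1")
    assert "BIGFAM:m2" not in eg
    eg_multi = ne.enrich(g, bigfam=members, multiple_models=True)
    assert eg_multi.has_edge("BGC:A1", "BIGFAM:m2")


def test_arts_nodes_never_merge_families():
    g = _two_family_graph()
    arts = [ne.ArtsHit("BGC:A1", "ARTS:p1", "core_model"),
            ne.ArtsHit("BGC:B1", "ARTS:p1", "core_model")]
    eg = ne.enrich(g, arts=arts)
    assignments = ne.enriched_gcfs(eg)
    assert summarize_gcfs(assignments)["n_components"] == 2
    # deleting every ARTS row changes nothing in the assignment
    no_arts = ne.enriched_gcfs(ne.enrich(g))
    assert assignments == no_arts


def test_enrich_unknown_bgc_reference_rejected():
    g = _two_family_graph()
    with pytest.raises(ValidationError, match="BGC:nope"):
        ne.enrich(g, arts=[ne.ArtsHit("BGC:nope", "ARTS:p", "core_model")])


def test_kcb_threshold_out_of_range_usage_error():
    with pytest.raises(UsageError):
        ne.enrich(_two_family_graph(), kcb_min_similarity=101)


def test_components_match_union_find_on_random_graphs():
    rng = np.random.default_rng(12)
    for trial in range(5):
        n = int(rng.integers(20, 201))
        records = [bgc(f"n{i}") for i in range(n)]
        n_edges = int(rng.integers(0, 2 * n))
        edges = []
        seen = set()
        for _ in range(n_edges):
            i, j = rng.choice(n, size=2, replace=False)
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            edges.append(
                ne.SimilarityEdge(f"BGC:n{i}", f"BGC:n{j}",
                                  float(round(rng.uniform(0, 1), 3)))
            )
        cutoff = 0.4
        g = ne.build_baseline(edges, records, cutoff)
        assignments = ne.baseline_gcfs(g)
        uf = UnionFind()
        for rec in records:
            uf.add(rec.bgc_id)
        for e in edges:
            if e.distance <= cutoff:
                uf.union(e.bgc_a, e.bgc_b)
        assert gcf_partition(assignments) == uf.partition()


def test_partition_property_every_bgc_exactly_once(small_pipeline):
    _, baseline, _, enriched = small_pipeline
    for assignments in (baseline, enriched):
        ids = [a.bgc_id for a in assignments]
        assert len(ids) == len(set(ids))
    assert {a.bgc_id for a in baseline} == {a.bgc_id for a in enriched}


def test_enrichment_never_increases_components_or_singletons(default_pipeline):
    _, baseline, _, enriched = default_pipeline
    sb, se = summarize_gcfs(baseline), summarize_gcfs(enriched)
    assert se["n_components"] <= sb["n_components"]
    assert se["n_singletons"] <= sb["n_singletons"]


def test_deterministic_under_row_permutation(small_fixture):
    data = small_fixture
    rng = np.random.default_rng(5)
    def shuffled(rows):
        rows = list(rows)
        order = rng.permutation(len(rows))
        return [rows[i] for i in order]

    g1 = ne.build_baseline(data.edges, data.bgcs, data.config.cutoff,
                           data.mibig_members)
    g2 = ne.build_baseline(shuffled(data.edges), shuffled(data.bgcs),
                           data.config.cutoff, data.mibig_members)
    e1 = ne.enrich(g1, kcb=data.kcb_hits, arts=data.arts_hits)
    e2 = ne.enrich(g2, kcb=shuffled(data.kcb_hits), arts=shuffled(data.arts_hits))
    assert ne.enriched_gcfs(e1) == ne.enriched_gcfs(e2)
    assert ne.baseline_gcfs(g1) == ne.baseline_gcfs(g2)


def test_gcf_numbering_by_smallest_member():
    records = [bgc("z"), bgc("a"), bgc("m")]
    assignments = ne.baseline_gcfs(ne.build_baseline([], records, 0.3))
    by_id = {a.bgc_id: a.gcf_id for a in assignments}
    assert by_id == {"BGC:a": "GCF_1", "BGC:m": "GCF_2", "BGC:z": "GCF_3"}


# --- categorize_bgcs ------------------------------------------------------

def test_categorize_no_hits_all_false():
    records = [bgc("A")]
    baseline = ne.baseline_gcfs(ne.build_baseline([], records, 0.3))
    (flags,) = ne.categorize_bgcs(records, baseline)
    assert (flags.antismash_known, flags.bigscape_known,
            flags.bigfam_match, flags.arts_match) == (False,) * 4


def test_categorize_flags_independent_and_monotone():
    records = [bgc("A"), bgc("B")]
    baseline = ne.baseline_gcfs(ne.build_baseline([], records, 0.3))
    base_flags = ne.categorize_bgcs(records, baseline)
    enriched_inputs = dict(
        kcb=[ne.KnownClusterHit("BGC:A", "MIBIG:BGC0000001", 95.0)],
        bigfam=[ne.BigfamMembership("BGC:A", "BIGFAM:m")],
        arts=[ne.ArtsHit("BGC:A", "ARTS:p", "core_model")],
    )
    flags = {f.bgc_id: f for f in
             ne.categorize_bgcs(records, baseline, **enriched_inputs)}
    assert flags["BGC:A"].antismash_known
    assert flags["BGC:A"].bigfam_match
    assert flags["BGC:A"].arts_match
    assert not flags["BGC:A"].bigscape_known  # baseline has no MIBiG node
    assert flags["BGC:B"] == base_flags[1]  # adding rows never unsets a flag
    counts = ne.category_counts(list(flags.values()))
    assert counts["n"].sum() == 2
    assert len(counts) == 16


def test_categorize_fixture_marginals(small_fixture, small_pipeline):
    data = small_fixture
    _, baseline, _, _ = small_pipeline
    flags = ne.categorize_bgcs(
        data.bgcs, baseline, kcb=data.kcb_hits,
        kcb_min_similarity=data.config.kcb_min_similarity,
        bigfam=data.bigfam_membership, arts=data.arts_hits,
    )
    # marginals computed independently from the planted tables
    kcb_pass = {h.bgc_id for h in data.kcb_hits
                if h.similarity_pct >= data.config.kcb_min_similarity}
    with_model = {m.bgc_id for m in data.bigfam_membership}
    with_arts = {h.bgc_id for h in data.arts_hits}
    assert sum(f.antismash_known for f in flags) == len(kcb_pass)
    assert sum(f.bigfam_match for f in flags) == len(with_model)
    assert sum(f.arts_match for f in flags) == len(with_arts)
    known_families = data.truth.true_known_families
    expected_bigscape_known = sum(
        1 for b in data.bgcs
        if data.truth.true_family_of[b.bgc_id] in known_families
    )
    assert sum(f.bigscape_known for f in flags) == expected_bigscape_known
    # none of the planted unknown-profile group carries a knowledge link
    unknown = data.truth.true_unknown_profile_set
    for f in flags:
        if f.bgc_id in unknown:
            assert not f.antismash_known and not f.bigfam_match


# --- select_by_profile ----------------------------------------------------

def test_select_by_profile_excludes_known():
    records = [bgc(f"x{i}") for i in range(6)]
    g = ne.build_baseline([], records, 0.3)
    arts = [ne.ArtsHit(r.bgc_id, "ARTS:PROF", "core_model") for r in records]
    kcb = [ne.KnownClusterHit("BGC:x0", "MIBIG:BGC0000001", 95.0)]
    members = [ne.BigfamMembership("BGC:x1", "BIGFAM:m")]
    eg = ne.enrich(g, kcb=kcb, bigfam=members, arts=arts)
    assert ne.select_by_profile(eg, "ARTS:PROF") == {r.bgc_id for r in records}
    assert ne.select_by_profile(eg, "ARTS:PROF", require_unknown=True) == {
        "BGC:x2", "BGC:x3", "BGC:x4", "BGC:x5",
    }


def test_select_missing_profile_warns_empty(caplog):
    g = ne.build_baseline([], [bgc("A")], 0.3)
    with caplog.at_level(logging.WARNING):
        assert ne.select_by_profile(g, "ARTS:nope") == set()
    assert "nope" in caplog.text


# --- hull_overlays --------------------------------------------------------

def _assignments_for(points_by_gcf):
    assignments = []
    layout = {}
    for i, (gcf_id, pts) in enumerate(sorted(points_by_gcf.items())):
        for j, p in enumerate(pts):
            bgc_id = f"BGC:{gcf_id}_{j}"
            layout[bgc_id] = p
            assignments.append(
                ne.GCFAssignment(bgc_id, gcf_id, False, "unknown")
            )
    return layout, assignments


def brute_force_hull_vertices(pts):
    """Extreme-point enumeration: p is a hull vertex iff it is not inside
    the hull of the others (checked by a half-plane test over all pairs)."""
    pts = [tuple(p) for p in pts]
    vertices = set()
    for a in pts:
        for b in pts:
            if a == b:
                continue
            # all points strictly on one side of line a-b => a,b on hull
            cross = [
                (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
                for p in pts
                if p != a and p != b
            ]
            if all(c >= -1e-12 for c in cross) or all(c <= 1e-12 for c in cross):
                vertices.add(a)
                vertices.add(b)
    return vertices


def test_square_hull_counterclockwise():
    layout, assignments = _assignments_for(
        {"GCF_1": [(0, 0), (1, 0), (1, 1), (0, 1)]}
    )
    ((gcf_id, verts),) = ne.hull_overlays(layout, assignments)
    assert gcf_id == "GCF_1"
    assert len(verts) == 4
    area2 = sum(
        verts[i][0] * verts[(i + 1) % 4][1] - verts[(i + 1) % 4][0] * verts[i][1]
        for i in range(4)
    )
    assert area2 > 0  # positive signed area == counterclockwise


def test_gcfs_of_size_two_or_less_omitted():
    layout, assignments = _assignments_for(
        {"GCF_1": [(0, 0), (1, 1)], "GCF_2": [(0, 0), (1, 0), (0, 1)]}
    )
    hulls = dict(ne.hull_overlays(layout, assignments))
    assert set(hulls) == {"GCF_2"}


def test_collinear_degenerates_to_two_vertices(caplog):
    layout, assignments = _assignments_for(
        {"GCF_1": [(0, 0), (1, 1), (2, 2), (3, 3)]}
    )
    with caplog.at_level(logging.WARNING):
        ((_, verts),) = ne.hull_overlays(layout, assignments)
    assert sorted(verts) == [(0.0, 0.0), (3.0, 3.0)]


def test_random_hull_matches_extreme_point_enumeration():
    rng = np.random.default_rng(9)
    pts = [tuple(map(float, rng.uniform(0, 10, size=2))) for _ in range(10)]
    layout, assignments = _assignments_for({"GCF_1": pts})
    ((_, verts),) = ne.hull_overlays(layout, assignments)
    assert set(verts) == brute_force_hull_vertices(pts)


def test_missing_layout_point_rejected():
    layout, assignments = _assignments_for(
        {"GCF_1": [(0, 0), (1, 0), (0, 1)]}
    )
    del layout["BGC:GCF_1_2"]
    with pytest.raises(ValidationError, match="BGC:GCF_1_2"):
        ne.hull_overlays(layout, assignments)
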