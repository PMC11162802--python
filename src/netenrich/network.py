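"""Knowledge-enriched BGC similarity networks and gene cluster families.

The baseline network is the BiG-SCAPE-style sequence similarity graph:
BGC nodes joined by edges whose distance falls at or below a cutoff
(default 0.3). A gene cluster family (GCF) is a connected component.

Enrichment adds typed reference nodes from three knowledge bases and
connects them to the BGCs that hit them:

* ``MIBIG`` — curated, experimentally characterised clusters, linked via
  KnownClusterBlast hits at or above a similarity threshold (default
  80%). A MIBiG node in a component marks the family as *known*.
* ``BIGFAM`` — precomputed global gene cluster family models, linked via
  query membership. Models whose genus composition is too diverse
  (top-genus share below 30%) are filtered out first, since their edges
  would bridge unrelated families.
* ``ARTS`` — resistance/core gene profile models. ARTS nodes are carried
  in the graph for prioritisation queries but are ignored when
  components are recomputed, so they never merge families.

Shared reference nodes merge baseline components: two families hitting
the same MIBiG entry or the same kept model collapse into one enriched
GCF. This is the dereplication step — the enriched component count is
never larger than the baseline count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .diversity import ModelDiversity
from .errors import UsageError, ValidationError
from .io import (
    ArtsHit,
    BGCRecord,
    BigfamMembership,
    KnownClusterHit,
    SimilarityEdge,
    ensure_prefix,
    NS_ARTS,
)

logger = logging.getLogger(__name__)

NODE_BGC = "BGC"
NODE_MIBIG = "MIBIG"
NODE_BIGFAM = "BIGFAM"
NODE_ARTS = "ARTS"

EDGE_BIGSCAPE = "BIGSCAPE"
EDGE_KCB = "KCB"
EDGE_BIGFAM_MEMBER = "BIGFAM_MEMBER"
EDGE_ARTS_HIT = "ARTS_HIT"


@dataclass(frozen=True)
class GCFAssignment:
    bgc_id: str
    gcf_id: str
    is_singleton: bool
    known_status: str  # "known" | "unknown"
    linked_mibig: frozenset = field(default_factory=frozenset)
    linked_models: frozenset = field(default_factory=frozenset)


@dataclass(frozen=True)
class BGCCategoryFlags:
    bgc_id: str
    antismash_known: bool
    bigscape_known: bool
    bigfam_match: bool
    arts_match: bool


@dataclass(frozen=True)
class ModelFilterDecision:
    model_id: str
    removed: bool
    reason: str  # "low_top_genus" | "high_shannon" | "kept"


def _node_type(graph: nx.Graph, node) -> str:
    return graph.nodes[node].get("node_type", NODE_BGC)


def build_baseline(
    edges: Sequence[SimilarityEdge],
    bgcs: Sequence[BGCRecord],
    cutoff: float = 0.3,
    mibig_members: Optional[set] = None,
) -> nx.Graph:
    """Build the baseline similarity graph at a distance cutoff.

    Every BGC becomes a node (isolated ones included); each edge with
    ``distance <= cutoff`` becomes a BIGSCAPE edge. Edge endpoints in
    *mibig_members* become MIBIG nodes — these are MIBiG reference BGCs
    that BiG-SCAPE itself co-clustered with the dataset.
    """
    if not 0.0 < cutoff <= 1.0:
        raise UsageError(f"cutoff {cutoff} outside (0, 1]")
    mibig_members = set(mibig_members or ())
    graph = nx.Graph()
    for rec in bgcs:
        graph.add_node(
            rec.bgc_id,
            node_type=NODE_BGC,
            genome_id=rec.genome_id,
            bgc_class=rec.bgc_class,
            on_contig_edge=rec.on_contig_edge,
        )
    known_ids = set(graph.nodes) | mibig_members
    offenders = sorted(
        {e.bgc_a for e in edges if e.bgc_a not in known_ids}
        | {e.bgc_b for e in edges if e.bgc_b not in known_ids}
    )
    if offenders:
        raise ValidationError(
            "edge endpoints absent from the BGC table and MIBiG member set: "
            + ", ".join(offenders)
        )
    for e in edges:
        if e.distance > cutoff:
            continue
        for endpoint in (e.bgc_a, e.bgc_b):
            if endpoint not in graph:
                graph.add_node(endpoint, node_type=NODE_MIBIG)
        graph.add_edge(e.bgc_a, e.bgc_b, edge_type=EDGE_BIGSCAPE, weight=e.distance)
    return graph


def _assignments_from_graph(graph: nx.Graph) -> list[GCFAssignment]:
    """Connected components -> GCF assignments, numbered deterministically
    by each component's smallest member bgc_id."""
    components = []
    for comp in nx.connected_components(graph):
        bgc_members = sorted(n for n in comp if _node_type(graph, n) == NODE_BGC)
        if not bgc_members:
            continue  # reference-only component carries no GCF
        mibig = frozenset(n for n in comp if _node_type(graph, n) == NODE_MIBIG)
        models = frozenset(n for n in comp if _node_type(graph, n) == NODE_BIGFAM)
        components.append((bgc_members, mibig, models))
    components.sort(key=lambda c: c[0][0])
    out: list[GCFAssignment] = []
    for i, (bgc_members, mibig, models) in enumerate(components, start=1):
        gcf_id = f"GCF_{i}"
        singleton = len(bgc_members) == 1 and not mibig and not models
        status = "known" if mibig else "unknown"
        for bgc_id in bgc_members:
            out.append(
                GCFAssignment(
                    bgc_id=bgc_id,
                    gcf_id=gcf_id,
                    is_singleton=singleton,
                    known_status=status,
                    linked_mibig=mibig,
                    linked_models=models,
                )
            )
    return out


def baseline_gcfs(graph: nx.Graph) -> list[GCFAssignment]:
    """GCFs of the baseline graph: components; known iff a MIBIG node is
    in the component."""
    bad = sorted(
        {
            _node_type(graph, n)
            for n in graph.nodes
            if _node_type(graph, n) not in (NODE_BGC, NODE_MIBIG)
        }
    )
    if bad:
        raise UsageError(
            f"baseline graph may only contain BGC/MIBIG nodes, found {bad}; "
            "use enriched_gcfs for enriched graphs"
        )
    return _assignments_from_graph(graph)


def filter_models(
    diversity: Sequence[ModelDiversity],
    min_top_share: float = 0.3,
    max_shannon: Optional[float] = None,
) -> list[ModelFilterDecision]:
    """Decide which models to drop before enrichment.

    A model is removed when its top-genus share falls below
    *min_top_share*, or (if *max_shannon* is set) its Shannon index
    exceeds it; the recorded reason is the first rule triggered.
    """
    if not 0.0 <= min_top_share <= 1.0:
        raise UsageError(f"min_top_share {min_top_share} outside [0, 1]")
    out = []
    for d in diversity:
        if d.top_genus_share < min_top_share:
            out.append(ModelFilterDecision(d.model_id, True, "low_top_genus"))
        elif max_shannon is not None and d.shannon_h > max_shannon:
            out.append(ModelFilterDecision(d.model_id, True, "high_shannon"))
        else:
            out.append(ModelFilterDecision(d.model_id, False, "kept"))
    return out


def _check_bgcs_present(graph: nx.Graph, ids: Iterable[str], source: str) -> None:
    offenders = sorted({i for i in ids if i not in graph})
    if offenders:
        raise ValidationError(
            f"{source} references BGCs absent from the graph: " + ", ".join(offenders)
        )


def enrich(
    graph: nx.Graph,
    kcb: Sequence[KnownClusterHit] = (),
    kcb_min_similarity: float = 80.0,
    bigfam: Sequence[BigfamMembership] = (),
    model_filter: Sequence[ModelFilterDecision] = (),
    arts: Sequence[ArtsHit] = (),
    multiple_models: bool = False,
) -> nx.Graph:
    """Return a copy of *graph* with knowledge-base nodes and edges added.

    * KCB edges (BGC–MIBIG) for hits with similarity >= threshold;
    * membership edges (BGC–BIGFAM) for models not removed by the filter
      (best hit only unless *multiple_models*);
    * ARTS_HIT edges (BGC–ARTS) for every ARTS hit.

    Baseline BIGSCAPE edges are untouched; MIBiG nodes already present
    from co-clustering merge with KCB-introduced ones by id.
    """
    if not 0.0 <= kcb_min_similarity <= 100.0:
        raise UsageError(f"kcb_min_similarity {kcb_min_similarity} outside [0, 100]")
    g = graph.copy()
    _check_bgcs_present(g, (h.bgc_id for h in kcb), "KnownClusterBlast table")
    _check_bgcs_present(g, (m.bgc_id for m in bigfam), "BiG-FAM membership table")
    _check_bgcs_present(g, (h.bgc_id for h in arts), "ARTS hit table")

    for hit in kcb:
        if hit.similarity_pct < kcb_min_similarity:
            continue
        if hit.mibig_id not in g:
            g.add_node(hit.mibig_id, node_type=NODE_MIBIG)
        g.add_edge(
            hit.bgc_id, hit.mibig_id, edge_type=EDGE_KCB, weight=hit.similarity_pct
        )

    removed = {d.model_id for d in model_filter if d.removed}
    seen_model_for: set[str] = set()
    for mem in bigfam:
        if mem.model_id in removed:
            continue
        if not multiple_models:
            if mem.bgc_id in seen_model_for:
                logger.warning(
                    "%s: extra BiG-FAM membership %s ignored (best hit only)",
                    mem.bgc_id,
                    mem.model_id,
                )
                continue
            seen_model_for.add(mem.bgc_id)
        if mem.model_id not in g:
            g.add_node(mem.model_id, node_type=NODE_BIGFAM)
        g.add_edge(
            mem.bgc_id, mem.model_id, edge_type=EDGE_BIGFAM_MEMBER, weight=1.0
        )

    for hit in arts:
        if hit.profile_id not in g:
            g.add_node(hit.profile_id, node_type=NODE_ARTS, category=hit.category)
        g.add_edge(
            hit.bgc_id, hit.profile_id, edge_type=EDGE_ARTS_HIT, weight=1.0
        )
    return g


def enriched_gcfs(
    graph: nx.Graph, ignore_types: frozenset = frozenset({NODE_ARTS})
) -> list[GCFAssignment]:
    """GCFs of the enriched graph.

    Components are computed on the subgraph excluding nodes of the
    ignored types (ARTS by default — prioritisation hints, not family
    evidence) and their incident edges.
    """
    keep = [n for n in graph.nodes if _node_type(graph, n) not in ignore_types]
    return _assignments_from_graph(graph.subgraph(keep))


def categorize_bgcs(
    bgcs: Sequence[BGCRecord],
    baseline: Sequence[GCFAssignment],
    kcb: Sequence[KnownClusterHit] = (),
    kcb_min_similarity: float = 80.0,
    bigfam: Sequence[BigfamMembership] = (),
    arts: Sequence[ArtsHit] = (),
) -> list[BGCCategoryFlags]:
    """Per-BGC knowledge-base flags (the treemap categorisation).

    * ``antismash_known`` — has a KnownClusterBlast hit at or above the
      similarity threshold;
    * ``bigscape_known`` — its baseline GCF contains a MIBiG node;
    * ``bigfam_match`` — has any BiG-FAM membership row;
    * ``arts_match`` — has any ARTS hit.
    """
    known_gcf = {a.bgc_id: a.known_status == "known" for a in baseline}
    kcb_pass = {h.bgc_id for h in kcb if h.similarity_pct >= kcb_min_similarity}
    has_model = {m.bgc_id for m in bigfam}
    has_arts = {h.bgc_id for h in arts}
    return [
        BGCCategoryFlags(
            bgc_id=rec.bgc_id,
            antismash_known=rec.bgc_id in kcb_pass,
            bigscape_known=known_gcf.get(rec.bgc_id, False),
            bigfam_match=rec.bgc_id in has_model,
            arts_match=rec.bgc_id in has_arts,
        )
        for rec in bgcs
    ]


def category_counts(flags: Sequence[BGCCategoryFlags]) -> pd.DataFrame:
    """2x2x2x2 contingency table of the four flags (treemap input)."""
    rows = []
    for a in (True, False):
        for b in (True, False):
            for f in (True, False):
                for r in (True, False):
                    n = sum(
                        1
                        for fl in flags
                        if (fl.antismash_known, fl.bigscape_known,
                            fl.bigfam_match, fl.arts_match) == (a, b, f, r)
                    )
                    rows.append(
                        {
                            "antismash_known": a,
                            "bigscape_known": b,
                            "bigfam_match": f,
                            "arts_match": r,
                            "n": n,
                        }
                    )
    return pd.DataFrame(rows)


def select_by_profile(
    graph: nx.Graph, profile_id: str, require_unknown: bool = False
) -> set[str]:
    """BGCs adjacent to an ARTS profile node.

    With *require_unknown*, restrict to BGCs with no KCB edge and no
    BiG-FAM membership edge in the graph — candidates with bioactivity
    hints but no knowledge-base match, the prioritisation set.
    """
    profile_id = ensure_prefix(profile_id, NS_ARTS)
    if profile_id not in graph:
        logger.warning("profile %s not present in graph; empty selection", profile_id)
        return set()
    selected = {
        n for n in graph.neighbors(profile_id) if _node_type(graph, n) == NODE_BGC
    }
    if require_unknown:
        linked_types = (EDGE_KCB, EDGE_BIGFAM_MEMBER)
        selected = {
            n
            for n in selected
            if not any(
                data.get("edge_type") in linked_types
                for _, _, data in graph.edges(n, data=True)
            )
        }
    return selected


def hull_overlays(
    layout: Mapping[str, tuple[float, float]],
    gcfs: Sequence[GCFAssignment],
) -> list[tuple[str, list[tuple[float, float]]]]:
    """Convex hull overlays for plotting GCFs on a 2D network layout.

    For each GCF with more than 2 BGC members, the convex hull of the
    member points, vertices in counterclockwise order. Smaller GCFs are
    omitted. Collinear member sets degenerate to their two extreme
    points, with a warning.
    """
    members: dict[str, list[str]] = {}
    for a in gcfs:
        members.setdefault(a.gcf_id, []).append(a.bgc_id)
    out: list[tuple[str, list[tuple[float, float]]]] = []
    for gcf_id in sorted(members, key=lambda g: int(g.split("_")[1])):
        ids = members[gcf_id]
        if len(ids) <= 2:
            continue
        missing = sorted(i for i in ids if i not in layout)
        if missing:
            raise ValidationError(
                f"{gcf_id}: no layout point for " + ", ".join(missing)
            )
        pts = np.asarray([layout[i] for i in ids], dtype=float)
        try:
            hull = ConvexHull(pts)
            verts = [tuple(pts[v]) for v in hull.vertices]
        except QhullError:
            logger.warning("%s: collinear points; degenerate 2-vertex hull", gcf_id)
            order = np.lexsort((pts[:, 1], pts[:, 0]))
            verts = [tuple(pts[order[0]]), tuple(pts[order[-1]])]
        out.append((gcf_id, verts))
    return out


def summarize_gcfs(assignments: Sequence[GCFAssignment]) -> dict:
    """Component / singleton / known summary of a GCF assignment."""
    by_gcf: dict[str, list[GCFAssignment]] = {}
    for a in assignments:
        by_gcf.setdefault(a.gcf_id, []).append(a)
    n_known = sum(1 for v in by_gcf.values() if v[0].known_status == "known")
    n_singletons = sum(1 for v in by_gcf.values() if v[0].is_singleton)
    mibig = set().union(*(v[0].linked_mibig for v in by_gcf.values())) if by_gcf else set()
    return {
        "n_bgcs": len(assignments),
        "n_components": len(by_gcf),
        "n_singletons": n_singletons,
        "n_known_gcfs": n_known,
        "n_known_bgcs": sum(1 for a in assignments if a.known_status == "known"),
        "n_linked_mibig": len(mibig),
    }
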