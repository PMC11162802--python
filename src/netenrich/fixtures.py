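"""Deterministic synthetic-data generator with planted ground truth.

The generator emulates the statistical structure of the canonical
upstream exports — a BGC table, a BiG-SCAPE-style edge list, a
KnownClusterBlast hit table, BiG-FAM membership and genus-count tables,
an ARTS hit table, and a MASH-style genome distance matrix — with the
truth planted so every downstream statistic is checkable:

* BGCs are partitioned into true families; within-family distances fall
  below the clustering cutoff, between-family distances above it, so the
  baseline components recover the partition exactly.
* A configurable fraction of families is linked to a MIBiG entry both by
  co-clustering (an edge to a MIBIG node) and by KnownClusterBlast hits.
* Pairs of families are planted to merge only after enrichment, via a
  shared MIBiG entry (KnownClusterBlast) or a shared kept BiG-FAM model.
* A configurable fraction of models gets a top-genus share below the
  removal threshold; their memberships span families and must not merge
  anything once the filter runs.
* One ARTS profile carries a group of BGCs with no knowledge-base links
  at all — the prioritisation target set.
* Genomes fall into distance blocks matching the true phylogroups.

Default sizes mirror the study conditions: 26 genomes with 13–40 BGC
regions each, 300 true families (mostly small, preferentially grown so
singletons dominate), ~1.5% of families MIBiG-linked, ~8% of models too
genus-diverse to keep, and a 17-member unknown-profile group.

Same seed, same config => byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as cio
from .errors import UsageError
from .io import (
    ArtsHit,
    BGCRecord,
    BigfamMembership,
    DistanceMatrix,
    GenusCount,
    KnownClusterHit,
    SimilarityEdge,
)

_GENUS_POOL = [
    "Saccharopolyspora",
    "Streptomyces",
    "Amycolatopsis",
    "Kitasatospora",
    "Nocardia",
    "Pseudomonas_E",
    "Mycobacterium",
    "Staphylococcus",
    "Acinetobacter",
    "Bacillus",
    "Corynebacterium",
    "Micromonospora",
    "Salinispora",
    "Rhodococcus",
    "Paenibacillus",
    "Burkholderia",
    "Actinomadura",
    "Frankia",
    "Nonomuraea",
    "Lentzea",
]

_BGC_CLASS_WEIGHTS = {
    # class frequencies shaped like the study dataset (724 BGCs)
    "Others": 243,
    "Terpene": 159,
    "RiPPs": 90,
    "NRPS": 82,
    "PKSother": 60,
    "PKSI": 45,
    "PKS-NRP_Hybrids": 37,
    "Saccharides": 8,
}


@dataclass(frozen=True)
class GenusProfileSpec:
    """Shape of per-model genus count tables.

    Kept models draw their top-genus share from ``top_share_range``;
    a ``frac_low_share`` fraction instead draws from
    ``low_share_range`` (below the 0.3 removal threshold). The
    remaining share decays geometrically over the other genera.
    """

    top_share_range: tuple[float, float] = (0.5, 0.95)
    low_share_range: tuple[float, float] = (0.08, 0.28)
    frac_low_share: float = 0.08
    n_genera_range: tuple[int, int] = (2, 12)
    model_size_range: tuple[int, int] = (40, 4000)


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 0
    n_genomes: int = 26
    n_bgcs_per_genome: tuple[int, int] = (13, 40)
    n_true_families: int = 300
    cutoff: float = 0.3
    within_family_distance: tuple[float, float] = (0.05, 0.25)
    between_family_distance: tuple[float, float] = (0.35, 0.95)
    frac_families_with_mibig_link: float = 0.015
    kcb_similarity_range: tuple[float, float] = (85.0, 99.0)
    kcb_min_similarity: float = 80.0
    n_bigfam_models: int = 40
    genus_profiles: GenusProfileSpec = field(default_factory=GenusProfileSpec)
    n_arts_profiles: int = 12
    planted_unknown_profile_group: int = 17
    unknown_profile_id: str = "ARTS:TIGR03997"
    n_kcb_merge_pairs: int = 2
    n_model_merge_pairs: int = 1
    n_phylogroups: int = 8
    within_group_distance: tuple[float, float] = (0.005, 0.05)
    between_group_distance: tuple[float, float] = (0.15, 0.45)

    def validate(self) -> None:
        lo_w, hi_w = self.within_family_distance
        lo_b, hi_b = self.between_family_distance
        if not (hi_w <= self.cutoff < lo_b):
            raise UsageError(
                "within/between distance ranges must be disjoint around the cutoff"
            )
        min_bgcs = self.n_genomes * self.n_bgcs_per_genome[0]
        if self.n_true_families > min_bgcs:
            raise UsageError("more true families than guaranteed BGCs")
        if self.n_phylogroups > self.n_genomes:
            raise UsageError("more phylogroups than genomes")
        n_merge = 2 * (self.n_kcb_merge_pairs + self.n_model_merge_pairs)
        n_linked = int(round(self.frac_families_with_mibig_link * self.n_true_families))
        if n_merge + n_linked > self.n_true_families:
            raise UsageError("not enough families for the planted links and merges")
        for frac in (self.frac_families_with_mibig_link,
                     self.genus_profiles.frac_low_share):
            if not 0.0 <= frac <= 1.0:
                raise UsageError(f"fraction {frac} outside [0, 1]")


@dataclass
class FixtureTruth:
    true_family_of: dict[str, str]
    true_known_families: set[str]
    true_enriched_merges: list[tuple[str, ...]]
    true_phylogroups: dict[str, str]
    true_unknown_profile_set: set[str]
    expected: dict


@dataclass
class FixtureData:
    config: FixtureConfig
    bgcs: list[BGCRecord]
    edges: list[SimilarityEdge]
    kcb_hits: list[KnownClusterHit]
    bigfam_membership: list[BigfamMembership]
    genus_counts: list[GenusCount]
    arts_hits: list[ArtsHit]
    distances: DistanceMatrix
    mibig_members: set[str]
    truth: FixtureTruth


class _UnionFind:
    """Generation-side bookkeeping for planted component structure."""

    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def generate(config: FixtureConfig, out_dir: Optional[Path] = None) -> FixtureData:
    """Generate all canonical tables plus planted ground truth.

    When *out_dir* is given, the canonical TSVs, the distance matrix and
    ``truth.json`` are written there (byte-identical for a fixed config).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- genomes and phylogroups -------------------------------------
    genomes = [f"G{i + 1:03d}" for i in range(config.n_genomes)]
    group_of = {g: i % config.n_phylogroups for i, g in enumerate(genomes)}
    true_phylogroups = {g: f"PG{group_of[g] + 1}" for g in genomes}

    n = config.n_genomes
    dvals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same = group_of[genomes[i]] == group_of[genomes[j]]
            lo, hi = (
                config.within_group_distance if same else config.between_group_distance
            )
            dvals[i, j] = dvals[j, i] = rng.uniform(lo, hi)
    distances = DistanceMatrix(ids=tuple(genomes), values=dvals)

    # --- BGCs and true families --------------------------------------
    classes = list(_BGC_CLASS_WEIGHTS)
    class_p = np.array(list(_BGC_CLASS_WEIGHTS.values()), dtype=float)
    class_p /= class_p.sum()
    bgc_ids: list[str] = []
    bgcs: list[BGCRecord] = []
    for g in genomes:
        n_regions = int(rng.integers(config.n_bgcs_per_genome[0],
                                     config.n_bgcs_per_genome[1] + 1))
        for r in range(n_regions):
            bgc_id = f"BGC:{g}.r{r + 1:03d}"
            bgc_ids.append(bgc_id)
            bgcs.append(
                BGCRecord(
                    bgc_id=bgc_id,
                    genome_id=g,
                    bgc_class=str(rng.choice(classes, p=class_p)),
                    on_contig_edge=bool(rng.random() < 0.2),
                )
            )

    families = [f"F{i + 1:03d}" for i in range(config.n_true_families)]
    order = rng.permutation(len(bgc_ids))
    family_members: dict[str, list[str]] = {f: [] for f in families}
    # seed each family with one BGC, then grow preferentially so the
    # family-size distribution is skewed toward singletons
    for i, f in enumerate(families):
        family_members[f].append(bgc_ids[order[i]])
    sizes = np.ones(len(families))
    for idx in order[len(families):]:
        probs = sizes / sizes.sum()
        fi = int(rng.choice(len(families), p=probs))
        family_members[families[fi]].append(bgc_ids[idx])
        sizes[fi] += 1
    true_family_of = {
        b: f for f, members in family_members.items() for b in members
    }

    # --- similarity edges --------------------------------------------
    wlo, whi = config.within_family_distance
    blo, bhi = config.between_family_distance
    edges: list[SimilarityEdge] = []
    seen_pairs: set[tuple[str, str]] = set()

    def add_edge(a: str, b: str, dist: float) -> None:
        key = (a, b) if a <= b else (b, a)
        if key not in seen_pairs:
            seen_pairs.add(key)
            edges.append(SimilarityEdge(key[0], key[1], round(float(dist), 4)))

    for members in family_members.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                add_edge(members[i], members[j], rng.uniform(wlo, whi))
    n_between = 2 * len(bgc_ids)
    for _ in range(n_between):
        a, b = rng.choice(len(bgc_ids), size=2, replace=False)
        fa, fb = true_family_of[bgc_ids[a]], true_family_of[bgc_ids[b]]
        if fa != fb:
            add_edge(bgc_ids[a], bgc_ids[b], rng.uniform(blo, bhi))

    # --- planted roles for families ----------------------------------
    n_linked = int(round(config.frac_families_with_mibig_link
                         * config.n_true_families))
    shuffled = list(rng.permutation(families))
    linked_families = shuffled[:n_linked]
    pos = n_linked
    kcb_pairs = []
    for _ in range(config.n_kcb_merge_pairs):
        kcb_pairs.append((shuffled[pos], shuffled[pos + 1]))
        pos += 2
    model_pairs = []
    for _ in range(config.n_model_merge_pairs):
        model_pairs.append((shuffled[pos], shuffled[pos + 1]))
        pos += 2
    plain_families = shuffled[pos:]

    # --- unknown-profile prioritisation group ------------------------
    # drawn from plain families so no knowledge-base link ever touches them
    unknown_set: list[str] = []
    reserved_families: list[str] = []
    for f in plain_families:
        if len(unknown_set) >= config.planted_unknown_profile_group:
            break
        take = family_members[f][: config.planted_unknown_profile_group
                                 - len(unknown_set)]
        unknown_set.extend(take)
        if take:
            reserved_families.append(f)
    if len(unknown_set) < config.planted_unknown_profile_group:
        raise UsageError("not enough unlinked BGCs for the unknown-profile group")
    unknown_bgcs = set(unknown_set)
    linkable_families = [f for f in plain_families if f not in reserved_families]

    # --- MIBiG co-clustering + KnownClusterBlast hits -----------------
    mibig_counter = 1
    mibig_members: set[str] = set()
    kcb_hits: list[KnownClusterHit] = []
    slo, shi = config.kcb_similarity_range

    def fresh_mibig() -> str:
        nonlocal mibig_counter
        mid = f"MIBIG:BGC{mibig_counter:07d}"
        mibig_counter += 1
        return mid

    for f in linked_families:
        mid = fresh_mibig()
        mibig_members.add(mid)
        add_edge(family_members[f][0], mid, rng.uniform(wlo, whi))
        for b in family_members[f]:
            kcb_hits.append(KnownClusterHit(b, mid, round(rng.uniform(slo, shi), 1)))
    for fa, fb in kcb_pairs:
        mid = fresh_mibig()
        kcb_hits.append(
            KnownClusterHit(family_members[fa][0], mid,
                            round(rng.uniform(slo, shi), 1))
        )
        kcb_hits.append(
            KnownClusterHit(family_members[fb][0], mid,
                            round(rng.uniform(slo, shi), 1))
        )
    # sub-threshold noise hits: present in the table, absent from the graph
    noise_candidates = [b for b in bgc_ids if b not in unknown_bgcs]
    n_noise = min(max(3, len(bgc_ids) // 40), len(noise_candidates))
    for b in rng.choice(noise_candidates, size=n_noise, replace=False):
        kcb_hits.append(
            KnownClusterHit(str(b), fresh_mibig(),
                            round(rng.uniform(10.0, 70.0), 1))
        )

    # --- BiG-FAM models: genus tables + memberships -------------------
    gp = config.genus_profiles
    n_low = int(round(gp.frac_low_share * config.n_bigfam_models))
    model_ids = [f"BIGFAM:{200000 + i}" for i in range(config.n_bigfam_models)]
    low_models = set(model_ids[:n_low])

    genus_counts: list[GenusCount] = []
    for mid in model_ids:
        n_genera = int(rng.integers(gp.n_genera_range[0], gp.n_genera_range[1] + 1))
        if mid in low_models:
            n_genera = max(n_genera, 5)  # need enough genera to dilute the top
            top = rng.uniform(*gp.low_share_range)
        else:
            top = rng.uniform(*gp.top_share_range)
        if n_genera == 1:
            top = 1.0
        size = int(rng.integers(gp.model_size_range[0], gp.model_size_range[1] + 1))
        genera = list(rng.choice(len(_GENUS_POOL), size=min(n_genera,
                                                            len(_GENUS_POOL)),
                                 replace=False))
        names = [_GENUS_POOL[i] for i in genera]
        while len(names) < n_genera:
            names.append(f"Genus_{len(names):02d}")
        shares = np.zeros(n_genera)
        shares[0] = top
        if n_genera > 1:
            # low-share models use a gentle tail so no single tail genus
            # dominates; kept models use a steep one (clear top genus)
            decay = 0.9 if mid in low_models else 0.5
            tail = decay ** np.arange(n_genera - 1)
            shares[1:] = (1.0 - top) * tail / tail.sum()
        counts = np.maximum(1, np.round(shares * size).astype(int))
        if mid in low_models and counts.max() / counts.sum() >= 0.3:
            # rounding pushed a genus over the removal threshold; fall
            # back to a near-uniform split, which is always below it
            base = max(1, size // n_genera)
            counts = np.full(n_genera, base, dtype=int)
        for name, count in zip(names, counts):
            genus_counts.append(GenusCount(mid, name, int(count)))

    membership: list[BigfamMembership] = []
    with_model: set[str] = set()

    def add_membership(bgc: str, mid: str) -> None:
        if bgc not in with_model:  # best-hit only: one row per BGC
            membership.append(BigfamMembership(bgc, mid))
            with_model.add(bgc)

    kept_models = [m for m in model_ids if m not in low_models]
    mpos = 0
    model_merge_models = []
    for fa, fb in model_pairs:
        mid = kept_models[mpos]
        mpos += 1
        model_merge_models.append(mid)
        add_membership(family_members[fa][0], mid)
        add_membership(family_members[fb][0], mid)
    # remaining kept models each cover members of one family
    for mid in kept_models[mpos:]:
        if not linkable_families:
            break
        f = linkable_families[int(rng.integers(len(linkable_families)))]
        for b in family_members[f][:3]:
            add_membership(b, mid)
    # low-share models span families; the filter must keep them inert
    for mid in sorted(low_models):
        picks = rng.choice(noise_candidates, size=min(4, len(noise_candidates)),
                           replace=False)
        for b in picks:
            add_membership(str(b), mid)

    # --- ARTS hits -----------------------------------------------------
    arts_hits: list[ArtsHit] = []
    arts_profiles = [f"ARTS:PF{i + 1:05d}" for i in range(config.n_arts_profiles)]
    for pid in arts_profiles:
        n_hits = min(int(rng.integers(2, 9)), len(bgc_ids))
        category = "resistance_model" if rng.random() < 0.4 else "core_model"
        for b in rng.choice(bgc_ids, size=n_hits, replace=False):
            arts_hits.append(ArtsHit(str(b), pid, category))
    # the planted prioritisation profile: the unknown group plus a couple
    # of knowledge-linked BGCs that require_unknown must exclude
    for b in unknown_set:
        arts_hits.append(ArtsHit(b, config.unknown_profile_id, "core_model"))
    decoys = [b for f in linked_families for b in family_members[f][:1]][:2]
    for b in decoys:
        arts_hits.append(ArtsHit(b, config.unknown_profile_id, "core_model"))
    # dedupe (profile hits drawn independently may repeat a pair)
    seen_hits: set[tuple[str, str]] = set()
    deduped: list[ArtsHit] = []
    for h in arts_hits:
        if (h.bgc_id, h.profile_id) not in seen_hits:
            seen_hits.add((h.bgc_id, h.profile_id))
            deduped.append(h)
    arts_hits = deduped

    # --- expected statistics (construction-side union-find) -----------
    uf = _UnionFind(families)
    threshold = config.kcb_min_similarity
    by_mibig: dict[str, list[str]] = {}
    for h in kcb_hits:
        if h.similarity_pct >= threshold:
            by_mibig.setdefault(h.mibig_id, []).append(true_family_of[h.bgc_id])
    by_model: dict[str, list[str]] = {}
    for m in membership:
        if m.model_id not in low_models:
            by_model.setdefault(m.model_id, []).append(true_family_of[m.bgc_id])
    for fams in list(by_mibig.values()) + list(by_model.values()):
        for other in fams[1:]:
            uf.union(fams[0], other)

    comp_of = {f: uf.find(f) for f in families}
    comp_members: dict[str, list[str]] = {}
    for f in families:
        comp_members.setdefault(comp_of[f], []).append(f)
    fam_has_mibig = set(linked_families) | {
        f for fams in by_mibig.values() for f in fams
    }
    fam_has_model = {f for fams in by_model.values() for f in fams}
    n_singletons_enriched = 0
    for root, fams in comp_members.items():
        n_bgcs_comp = sum(len(family_members[f]) for f in fams)
        has_ref = any(f in fam_has_mibig or f in fam_has_model for f in fams)
        if n_bgcs_comp == 1 and not has_ref:
            n_singletons_enriched += 1
    n_known_enriched = sum(
        1
        for fams in comp_members.values()
        if any(f in fam_has_mibig for f in fams)
    )
    baseline_singletons = sum(
        1
        for f in families
        if len(family_members[f]) == 1 and f not in linked_families
    )

    expected = {
        "n_bgcs": len(bgc_ids),
        "baseline_components": config.n_true_families,
        "baseline_singletons": baseline_singletons,
        "baseline_known": len(linked_families),
        "enriched_components": len(comp_members),
        "enriched_singletons": n_singletons_enriched,
        "enriched_known": n_known_enriched,
        "n_phylogroups": config.n_phylogroups,
        "unknown_profile_group": config.planted_unknown_profile_group,
    }

    truth = FixtureTruth(
        true_family_of=true_family_of,
        true_known_families=set(linked_families),
        true_enriched_merges=[tuple(p) for p in kcb_pairs + model_pairs],
        true_phylogroups=true_phylogroups,
        true_unknown_profile_set=set(unknown_set),
        expected=expected,
    )
    data = FixtureData(
        config=config,
        bgcs=bgcs,
        edges=edges,
        kcb_hits=kcb_hits,
        bigfam_membership=membership,
        genus_counts=genus_counts,
        arts_hits=arts_hits,
        distances=distances,
        mibig_members=mibig_members,
        truth=truth,
    )
    if out_dir is not None:
        _write_fixture(data, Path(out_dir))
    return data


def _write_fixture(data: FixtureData, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cio.write_table(data.bgcs, out_dir / "bgcs.tsv", "bgcs")
    cio.write_table(data.edges, out_dir / "edges.tsv", "edges")
    cio.write_table(data.kcb_hits, out_dir / "kcb_hits.tsv", "kcb_hits")
    cio.write_table(
        data.bigfam_membership, out_dir / "bigfam_membership.tsv",
        "bigfam_membership",
    )
    cio.write_table(
        data.genus_counts, out_dir / "bigfam_genus_counts.tsv",
        "bigfam_genus_counts",
    )
    cio.write_table(data.arts_hits, out_dir / "arts_hits.tsv", "arts_hits")
    cio.write_distance_matrix(data.distances, out_dir / "distances.tsv")
    truth = data.truth
    payload = {
        "true_family_of": truth.true_family_of,
        "true_known_families": sorted(truth.true_known_families),
        "true_enriched_merges": [list(p) for p in truth.true_enriched_merges],
        "true_phylogroups": truth.true_phylogroups,
        "true_unknown_profile_set": sorted(truth.true_unknown_profile_set),
        "mibig_members": sorted(data.mibig_members),
        "expected": truth.expected,
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
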