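# Methods

## Scope and data model

`netenrich` operates on canonical tabular exports of the standard
genome-mining tools, re-specified here as plain TSVs with fixed headers
(`bgcs.tsv`, `edges.tsv`, `kcb_hits.tsv`, `bigfam_membership.tsv`,
`bigfam_genus_counts.tsv`, `arts_hits.tsv`, plus a square distance
matrix). Upstream tool dialects drift across versions, so the TSV
schemas defined in `netenrich.io` are normative and adapters are out of
scope. All identifiers are namespace-prefixed at ingest (`BGC:`,
`MIBIG:`, `BIGFAM:`, `ARTS:`): four id spaces are merged into one graph,
and the prefixes make collisions impossible by construction.

## Baseline network and GCFs

The baseline graph has one node per BGC (isolated BGCs included) and an
undirected BIGSCAPE edge for each pair with distance `d ≤ cutoff`. The
cutoff is inclusive and defaults to 0.3; distances follow the
"smaller is more similar" convention throughout. MIBiG reference BGCs
that the similarity tool itself co-clustered can be passed as members
and appear as MIBIG nodes on BIGSCAPE edges. A GCF is a connected
component; components are numbered `GCF_1, GCF_2, …` by the
lexicographically smallest member BGC id, which makes labels a pure
function of the input content (row order never matters).

## Enrichment

`enrich` copies the baseline graph and adds, in order:

1. **KCB edges** (BGC–MIBIG) for KnownClusterBlast hits with
   `similarity ≥ 80%`. The threshold is inclusive and configurable.
   MIBiG nodes introduced here share ids with co-clustered ones, so the
   two evidence paths merge on one node.
2. **Membership edges** (BGC–BIGFAM) for models that survive the
   diversity filter (below). By default one membership per BGC is kept
   (the first row, mirroring a best-hit query); `multiple_models=True`
   keeps all.
3. **ARTS_HIT edges** (BGC–ARTS) for every profile hit.

Enriched GCFs are components of the subgraph excluding ARTS nodes (and
their incident edges): ARTS profiles flag potential bioactivity but are
deliberately not family evidence. A component's family is **known** iff
it contains at least one MIBIG node. A **singleton** is a component with
exactly one BGC node and no MIBIG/BIGFAM node — a BGC attached only to
reference nodes is assigned, not orphaned. Because enrichment only adds
nodes and edges, the number of BGC components and the number of
singletons can only decrease relative to baseline; both facts are
property-tested.

## Genus-diversity filter for global models

A BiG-FAM-style model carries a genus count table. With proportions
`p_i = c_i / Σc` over genera with `c_i > 0`, the Shannon index is
`H = −Σ p_i ln p_i` in nats, so `H = 0` for a single genus and
`H = ln R` for a uniform spread over `R` genera. The default removal
rule is purely compositional: a model is removed when its top-genus
share is below `0.3`. An optional `max_shannon` cap can be enabled, but
is off by default because the top-share rule is the one with a stated
operating point; when both trigger, the recorded reason is the first
rule (`low_top_genus`). Top-genus ties resolve to the lexicographically
smallest name with a warning.

## Categorisation and prioritisation

`categorize_bgcs` computes four independent per-BGC flags —
`antismash_known` (a KCB hit at/above threshold), `bigscape_known`
(baseline family contains a MIBiG node), `bigfam_match` (any membership
row, before filtering: this reflects the raw query), `arts_match` (any
profile hit) — and `category_counts` tabulates the 2×2×2×2 table for
treemap-style summaries. `select_by_profile` returns BGCs adjacent to a
given ARTS node; with `require_unknown=True` it drops every BGC with a
KCB or membership edge in the graph, leaving the unexplained candidates.

## Genome QC

`assembly_stats` computes total length, contig count, N50 and GC from
FASTA (plain or gzipped). N50 is the length at which the
descending-sorted cumulative contig-length sum first reaches half the
total; a cumulative sum exactly at half resolves to that contig.
Ambiguity code `N` counts toward contig lengths (and hence N50) but is
excluded from the GC denominator; other IUPAC codes count as non-GC with
a warning. Two classification policies are provided because the two
published rule sets disagree:

| policy | HQ | MQ | LQ |
|---|---|---|---|
| `results_policy` (default) | N50 > 5 Mb | contigs < 50 | otherwise |
| `methods_policy` | level ∈ {complete genome, chromosome} | contigs < 50 and N50 > 100 kb | otherwise |

All inequalities are strict exactly as printed, and each policy is
total: every assembly maps to exactly one class.

## Phylogrouping

Genomes are clustered by average-linkage agglomerative clustering on the
validated distance matrix (symmetric, non-negative, zero diagonal),
cutting the dendrogram at `k` groups. Labels `P1…Pk` are assigned by the
order of each cluster's first member in input order, so the partition —
the tested object — is order-invariant while labels stay deterministic.

When `k` is not supplied it is chosen over `k_range` (default 2–10,
clipped to `[2, n−1]`) by an elbow criterion on the score `s(k)` = mean
pairwise distance pooled over all within-cluster pairs. Pooling (rather
than summing per-cluster means) makes `s(k)` decline roughly linearly
while clusters still straddle planted groups and flatten once they are
pure, so the maximum second difference `s(k−1) − 2s(k) + s(k+1)` lands
on the planted `k`; ties resolve to the smaller `k`. The curve is
anchored with `s(1)` (the whole-set mean) and extended one step past the
range top so every candidate has both neighbours. If all off-diagonal
distances are equal the clustering is degenerate: the lower bound of the
range is returned with a warning. No printed selection score exists to
validate the auto-`k` rule against, so it is validated exclusively
against planted partitions.

## Synthetic data generator

`netenrich.fixtures.generate` emits every canonical table plus
`truth.json` with the planted ground truth, and is deterministic to the
byte for a fixed config. What it emulates:

* **Family structure** — BGCs partitioned into true families; all
  within-family pairs get distances uniform in (0.05, 0.25), sampled
  between-family pairs uniform in (0.35, 0.95). The ranges are disjoint
  around the 0.3 cutoff so threshold behaviour is exercised without
  modelling real distance distributions.
* **Family sizes** — one seed BGC per family, remaining BGCs attached
  preferentially (probability ∝ current size), giving the
  singleton-heavy size distribution real datasets show.
* **Knowledge links** — a configurable fraction of families is
  MIBiG-linked (co-clustered edge + member KCB hits ≥ 85%); planted
  pairs of families share a fresh MIBiG entry (KCB only) or a kept
  BiG-FAM model, producing enrichment-only merges recorded in the
  truth; sub-threshold KCB noise hits are present in tables but must
  stay out of the graph.
* **Model compositions** — kept models draw a top-genus share in
  (0.5, 0.95) with a steep geometric tail; a configurable fraction
  draws (0.08, 0.28) with a gentle tail so every genus stays below the
  0.3 removal threshold. Kept models link members of a single family
  (merging is reserved for the planted pairs); low-share models span
  families, so the filter must keep them inert.
* **Prioritisation group** — a planted set of BGCs (default 17) shares
  one ARTS profile and receives no KCB hit or model membership; two
  knowledge-linked decoys sit on the same profile to exercise the
  unknown filter.
* **Phylogroups** — genomes assigned round-robin to groups; block
  distances uniform in (0.005, 0.05) within and (0.15, 0.45) between.

Default sizes mirror the study conditions: 26 genomes, 13–40 regions
each (~670 BGCs), 300 families, ~1.5% MIBiG-linked, 40 models with 8%
low-share, 8 phylogroups, a 17-member unknown-profile group. The
expected statistics in `truth.json` are derived on the generation side
with an independent union-find over planted link evidence, not by
running the pipeline.

What the generator does **not** emulate: nucleotide sequences, real
BiG-SCAPE distance distributions (only their order relative to the
cutoff), upstream tool output dialects, correlated noise between
evidence layers, or mis-assembly artefacts. Passing tests therefore
demonstrate the correctness of the graph algebra, thresholds and
bookkeeping under separable planted structure — not robustness to
borderline distances near the cutoff, which real data can produce.

## Numerical and degenerate-input choices

* Distances are validated into `[0, 1]` at ingest; duplicate unordered
  edge pairs are deduplicated with a warning (first occurrence wins).
* Empty assemblies, empty contigs, all-zero genus counts, unknown
  policies/formats/schemas raise typed errors (`ValidationError` /
  `UsageError` / `SchemaError`).
* Convex hull overlays are computed only for families with more than
  two members; collinear point sets degenerate to the two extreme
  points with a warning; vertices are returned counterclockwise.
* Matrix symmetry checks use an absolute tolerance of 1e-9.

## Problem sizes

The test suite and the acceptance script run the full pipeline on the
default synthetic dataset (~670 BGCs, ~900 edges, 26 genomes) plus a
small 12-family variant; both complete in seconds. These sizes exercise
every code path — component merging, filtering, prioritisation,
auto-`k` — while keeping the suite fast enough to run on every change.

## Known limitations

* The enriched-network semantics assume best-hit model membership by
  default; with `multiple_models=True` heavily shared models can chain
  many families, and no safeguard beyond the diversity filter exists.
* Auto-`k` assumes a block-like distance structure; for gradient-like
  structure the elbow is weakly identified and an explicit `k` is the
  honest choice.
* `bigfam_match` in categorisation reflects the raw query (pre-filter),
  while graph membership edges are post-filter; the two views answer
  different questions and are intentionally not identical.
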