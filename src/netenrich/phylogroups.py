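"""Distance-based phylogrouping of genomes.

Genomes are grouped from a pairwise distance matrix (typically MASH
distances) by average-linkage agglomerative clustering, cutting the tree
at k groups. Phylogroups sit between genus and species rank: close
enough to share most gene content, far enough to be distinguishable by
whole-genome sketch distance.

When k is not given it is chosen automatically over a candidate range by
the elbow of the total within-cluster mean pairwise distance: the score
s(k) sums, over clusters, the mean pairwise distance among members
(singletons contribute 0). The chosen k maximises the discrete second
difference s(k-1) - 2 s(k) + s(k+1); ties resolve to the smaller k.
s(1) (the whole-set mean pairwise distance) anchors the curve so the
lower bound of the range is a valid candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import UsageError, ValidationError
from .io import DistanceMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhylogroupAssignment:
    genome_id: str
    phylogroup: str
    chosen_k: int


def _within_score(values: np.ndarray, labels: np.ndarray) -> float:
    """Mean pairwise distance pooled over all within-cluster pairs.

    Pooling (rather than averaging per-cluster means) makes the score
    decline roughly linearly in k while clusters still straddle planted
    groups and flatten once they are pure, so the elbow sits at the
    planted k. Zero when no within pairs remain (all singletons).
    """
    total = 0.0
    n_pairs = 0
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if len(members) < 2:
            continue
        sub = values[np.ix_(members, members)]
        iu = np.triu_indices(len(members), k=1)
        total += float(sub[iu].sum())
        n_pairs += len(iu[0])
    return total / n_pairs if n_pairs else 0.0


def _relabel_first_appearance(raw: np.ndarray) -> list[str]:
    """Map raw cluster ids to P1, P2, ... by order of first appearance."""
    mapping: dict[int, str] = {}
    for lab in raw:
        if lab not in mapping:
            mapping[lab] = f"P{len(mapping) + 1}"
    return [mapping[lab] for lab in raw]


def cluster_phylogroups(
    d: DistanceMatrix,
    k: int | None = None,
    k_range: tuple[int, int] = (2, 10),
) -> list[PhylogroupAssignment]:
    """Assign each genome to a phylogroup label P1..Pk.

    Parameters
    ----------
    d
        Validated square symmetric distance matrix.
    k
        Number of groups; when ``None`` it is chosen from ``k_range``.
    k_range
        Inclusive (low, high) candidate interval for automatic k;
        clipped to [2, n-1].
    """
    n = len(d.ids)
    values = np.asarray(d.values, dtype=float)
    if k is None and n < 3:
        raise UsageError("automatic k needs at least 3 genomes; pass k explicitly")
    if k is not None:
        if not 2 <= k <= n - 1:
            raise UsageError(f"k={k} outside [2, {n - 1}]")
    condensed = squareform(values, checks=False)
    tree = linkage(condensed, method="average")

    if k is None:
        lo = max(2, k_range[0])
        hi = min(n - 1, k_range[1])
        if lo > hi:
            raise UsageError(f"k_range {k_range} infeasible for n={n}")
        off_diag = condensed
        if off_diag.size and np.allclose(off_diag, off_diag[0]):
            logger.warning(
                "all pairwise distances equal; clustering degenerate, "
                "returning k=%d (lower bound of range)",
                lo,
            )
            k = lo
        else:
            scores: dict[int, float] = {1: _within_score(values, np.zeros(n, dtype=int))}
            for kk in range(lo, min(hi + 1, n) + 1):
                labels = fcluster(tree, t=kk, criterion="maxclust")
                scores[kk] = _within_score(values, labels)
            best_k, best_curv = None, -np.inf
            for kk in range(lo, hi + 1):
                prev = scores.get(kk - 1)
                nxt = scores.get(kk + 1)
                if prev is None or nxt is None:
                    continue
                curv = prev - 2.0 * scores[kk] + nxt
                if curv > best_curv + 1e-12:
                    best_k, best_curv = kk, curv
            if best_k is None:
                best_k = lo
            k = best_k

    raw = fcluster(tree, t=k, criterion="maxclust")
    found = len(np.unique(raw))
    if found != k:
        logger.warning("requested k=%d but tree cut yields %d groups", k, found)
        k = found
    labels = _relabel_first_appearance(raw)
    return [
        PhylogroupAssignment(genome_id=gid, phylogroup=lab, chosen_k=k)
        for gid, lab in zip(d.ids, labels)
    ]


def partition_of(assignments: list[PhylogroupAssignment]) -> dict[str, set[str]]:
    """Group genome ids by phylogroup label (order-invariant view)."""
    out: dict[str, set[str]] = {}
    for a in assignments:
        out.setdefault(a.phylogroup, set()).add(a.genome_id)
    return out
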