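"""Assembly statistics and genome quality classification.

Two published rule sets are supported as named policies:

``results_policy``
    HQ iff N50 > 5 Mb; otherwise MQ iff the assembly has fewer than 50
    contigs; otherwise LQ. This policy needs nothing beyond the contig
    statistics and is the default.

``methods_policy``
    HQ iff the declared assembly level is "complete genome" or
    "chromosome"; otherwise MQ iff fewer than 50 contigs AND N50 above
    100 kb; otherwise LQ. Requires assembly-level metadata for HQ calls.

All inequalities are strict exactly as printed; the boundaries are part
of the contract and are exercised in the test suite.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

from .errors import UsageError, ValidationError

logger = logging.getLogger(__name__)

QUALITY_CLASSES = ("HQ", "MQ", "LQ")
POLICIES = ("results_policy", "methods_policy")

#: Assembly levels that count as HQ under the methods policy.
HQ_ASSEMBLY_LEVELS = frozenset({"complete genome", "chromosome"})


@dataclass(frozen=True)
class AssemblyStats:
    genome_id: str
    total_length: int
    n_contigs: int
    n50: int
    gc_fraction: float


def n50(lengths: Sequence[int]) -> int:
    """N50: the length at which the descending cumulative contig-length
    sum first reaches half the total assembly length."""
    if not lengths:
        raise ValidationError("cannot compute N50 of an empty assembly")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2.0
    running = 0
    for length in ordered:
        running += length
        if running >= half:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


_GC = set("GCgc")
_AT = set("ATat")
_N = set("Nn")


def assembly_stats(contigs: Iterable[str], genome_id: str) -> AssemblyStats:
    """Compute contig statistics from nucleotide sequences.

    Lengths are raw record lengths (``N`` counts toward total length and
    N50). GC fraction is (G+C)/(A+C+G+T): ``N`` is excluded from the
    denominator, and any other IUPAC ambiguity code is counted as non-GC
    with a warning.
    """
    lengths: list[int] = []
    gc = 0
    atgc = 0
    warned = False
    for i, seq in enumerate(contigs):
        seq = str(seq)
        if not seq:
            raise ValidationError(f"{genome_id}: contig record {i + 1} is empty")
        lengths.append(len(seq))
        for base in seq:
            if base in _GC:
                gc += 1
                atgc += 1
            elif base in _AT:
                atgc += 1
            elif base in _N:
                continue
            else:
                # other IUPAC letters: denominator yes, GC no
                atgc += 1
                if not warned:
                    logger.warning(
                        "%s: ambiguous IUPAC code %r counted as non-GC",
                        genome_id,
                        base,
                    )
                    warned = True
    if not lengths:
        raise ValidationError(f"{genome_id}: no contigs provided")
    total = sum(lengths)
    return AssemblyStats(
        genome_id=genome_id,
        total_length=total,
        n_contigs=len(lengths),
        n50=n50(lengths),
        gc_fraction=(gc / atgc) if atgc else 0.0,
    )


def assembly_stats_from_fasta(path, genome_id: Optional[str] = None) -> AssemblyStats:
    """Compute :func:`assembly_stats` from a (optionally gzipped) FASTA file."""
    path = Path(path)
    if genome_id is None:
        genome_id = path.name
        for suffix in (".gz", ".fasta", ".fa", ".fna"):
            if genome_id.endswith(suffix):
                genome_id = genome_id[: -len(suffix)]
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        seqs = [str(rec.seq) for rec in SeqIO.parse(handle, "fasta")]
    if not seqs:
        raise ValidationError(f"{path}: no FASTA records found")
    return assembly_stats(seqs, genome_id)


def classify_quality(
    stats: AssemblyStats,
    policy: str = "results_policy",
    assembly_level: Optional[str] = None,
) -> str:
    """Assign HQ/MQ/LQ under the named policy. Total: every input maps to
    exactly one class."""
    if policy == "results_policy":
        if stats.n50 > 5_000_000:
            return "HQ"
        if stats.n_contigs < 50:
            return "MQ"
        return "LQ"
    if policy == "methods_policy":
        level = (assembly_level or "").strip().lower()
        if level in HQ_ASSEMBLY_LEVELS:
            return "HQ"
        if stats.n_contigs < 50 and stats.n50 > 100_000:
            return "MQ"
        return "LQ"
    raise UsageError(f"unknown quality policy {policy!r}; one of {POLICIES}")
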