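"""Readers and writers for the canonical tabular formats.

Every downstream module consumes the typed records defined here. The
canonical formats are plain TSV with a mandatory header; identifiers are
namespace-prefixed at ingest time (``BGC:``, ``MIBIG:``, ``BIGFAM:``,
``ARTS:``) so that the four identifier spaces can never collide when they
are merged into one heterogeneous graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import SchemaError, UsageError, ValidationError

logger = logging.getLogger(__name__)

#: BiG-SCAPE's closed vocabulary of BGC product classes.
BGC_CLASSES = frozenset(
    {
        "PKSI",
        "PKSother",
        "NRPS",
        "RiPPs",
        "Terpene",
        "Saccharides",
        "PKS-NRP_Hybrids",
        "Others",
    }
)

#: ARTS hit categories: resistance gene models and phylum core gene models.
ARTS_CATEGORIES = frozenset({"resistance_model", "core_model"})

NS_BGC = "BGC"
NS_MIBIG = "MIBIG"
NS_BIGFAM = "BIGFAM"
NS_ARTS = "ARTS"


def ensure_prefix(identifier: str, namespace: str) -> str:
    """Return *identifier* with ``<namespace>:`` prepended unless present."""
    identifier = str(identifier).strip()
    if not identifier:
        raise ValidationError(f"empty identifier in namespace {namespace}")
    if identifier.startswith(namespace + ":"):
        return identifier
    return f"{namespace}:{identifier}"


@dataclass(frozen=True)
class BGCRecord:
    bgc_id: str
    genome_id: str
    bgc_class: str
    on_contig_edge: bool


@dataclass(frozen=True)
class SimilarityEdge:
    bgc_a: str
    bgc_b: str
    distance: float


@dataclass(frozen=True)
class KnownClusterHit:
    bgc_id: str
    mibig_id: str
    similarity_pct: float


@dataclass(frozen=True)
class BigfamMembership:
    bgc_id: str
    model_id: str


@dataclass(frozen=True)
class GenusCount:
    model_id: str
    genus: str
    count: int


@dataclass(frozen=True)
class ArtsHit:
    bgc_id: str
    profile_id: str
    category: str


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric genome distance matrix (MASH-style)."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        n = len(self.ids)
        if vals.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {vals.shape} does not match {n} ids"
            )
        if np.any(vals < 0):
            raise ValidationError("distance matrix contains negative entries")
        if not np.allclose(vals, vals.T, atol=1e-9):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(vals), 0.0, atol=1e-9):
            raise ValidationError("distance matrix diagonal is not zero")


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _parse_bool(value, row: int, column: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValidationError(f"row {row}: {column}={value!r} is not a boolean")


SCHEMAS: dict[str, tuple[str, ...]] = {
    "bgcs": ("bgc_id", "genome_id", "bgc_class", "on_contig_edge"),
    "edges": ("bgc_a", "bgc_b", "distance"),
    "kcb_hits": ("bgc_id", "mibig_id", "similarity_pct"),
    "bigfam_membership": ("bgc_id", "model_id"),
    "bigfam_genus_counts": ("model_id", "genus", "count"),
    "arts_hits": ("bgc_id", "profile_id", "category"),
}


def _load_frame(path, schema: str) -> pd.DataFrame:
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; one of {sorted(SCHEMAS)}")
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SCHEMAS[schema] if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: schema {schema!r} is missing column(s) {', '.join(missing)}"
        )
    return frame.loc[:, list(SCHEMAS[schema])]


def read_table(path, schema: str) -> list:
    """Read a canonical TSV into a list of validated typed records.

    Row numbers in error messages count the header as line 1, matching
    what an editor shows for the file.
    """
    frame = _load_frame(path, schema)
    reader = _SCHEMA_READERS[schema]
    return reader(frame)


def _read_bgcs(frame: pd.DataFrame) -> list[BGCRecord]:
    records: list[BGCRecord] = []
    seen: set[str] = set()
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        bgc_id = ensure_prefix(row.bgc_id, NS_BGC)
        if bgc_id in seen:
            raise ValidationError(f"row {idx}: duplicate bgc_id {bgc_id}")
        seen.add(bgc_id)
        if row.bgc_class not in BGC_CLASSES:
            raise ValidationError(
                f"row {idx}: bgc_class {row.bgc_class!r} not in "
                f"{sorted(BGC_CLASSES)}"
            )
        records.append(
            BGCRecord(
                bgc_id=bgc_id,
                genome_id=str(row.genome_id),
                bgc_class=row.bgc_class,
                on_contig_edge=_parse_bool(row.on_contig_edge, idx, "on_contig_edge"),
            )
        )
    return records


def _read_edges(frame: pd.DataFrame) -> list[SimilarityEdge]:
    records: list[SimilarityEdge] = []
    seen: dict[tuple[str, str], int] = {}
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        a = str(row.bgc_a).strip()
        b = str(row.bgc_b).strip()
        # Endpoints may live in the BGC or the MIBiG id space; ids already
        # carrying a namespace are preserved, bare ids default to BGC.
        a = a if ":" in a else ensure_prefix(a, NS_BGC)
        b = b if ":" in b else ensure_prefix(b, NS_BGC)
        try:
            dist = float(row.distance)
        except (TypeError, ValueError):
            raise ValidationError(f"row {idx}: distance {row.distance!r} not numeric")
        if not 0.0 <= dist <= 1.0:
            raise ValidationError(f"row {idx}: distance {dist} outside [0, 1]")
        if a == b:
            raise ValidationError(f"row {idx}: self-loop on {a}")
        key = (a, b) if a <= b else (b, a)
        if key in seen:
            logger.warning(
                "duplicate unordered pair (%s, %s) at row %d; first occurrence kept",
                a,
                b,
                idx,
            )
            continue
        seen[key] = idx
        records.append(SimilarityEdge(bgc_a=a, bgc_b=b, distance=dist))
    return records


def _read_kcb_hits(frame: pd.DataFrame) -> list[KnownClusterHit]:
    records: list[KnownClusterHit] = []
    seen: set[tuple[str, str]] = set()
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        bgc_id = ensure_prefix(row.bgc_id, NS_BGC)
        mibig_id = ensure_prefix(row.mibig_id, NS_MIBIG)
        try:
            sim = float(row.similarity_pct)
        except (TypeError, ValueError):
            raise ValidationError(
                f"row {idx}: similarity_pct {row.similarity_pct!r} not numeric"
            )
        if not 0.0 <= sim <= 100.0:
            raise ValidationError(f"row {idx}: similarity_pct {sim} outside [0, 100]")
        key = (bgc_id, mibig_id)
        if key in seen:
            raise ValidationError(f"row {idx}: duplicate hit {bgc_id} -> {mibig_id}")
        seen.add(key)
        records.append(
            KnownClusterHit(bgc_id=bgc_id, mibig_id=mibig_id, similarity_pct=sim)
        )
    return records


def _read_bigfam_membership(frame: pd.DataFrame) -> list[BigfamMembership]:
    records: list[BigfamMembership] = []
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        records.append(
            BigfamMembership(
                bgc_id=ensure_prefix(row.bgc_id, NS_BGC),
                model_id=ensure_prefix(row.model_id, NS_BIGFAM),
            )
        )
    return records


def _read_genus_counts(frame: pd.DataFrame) -> list[GenusCount]:
    records: list[GenusCount] = []
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            count = int(row.count)
        except (TypeError, ValueError):
            raise ValidationError(f"row {idx}: count {row.count!r} not an integer")
        if count < 0:
            raise ValidationError(f"row {idx}: negative count {count}")
        records.append(
            GenusCount(
                model_id=ensure_prefix(row.model_id, NS_BIGFAM),
                genus=str(row.genus),
                count=count,
            )
        )
    return records


def _read_arts_hits(frame: pd.DataFrame) -> list[ArtsHit]:
    records: list[ArtsHit] = []
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        if row.category not in ARTS_CATEGORIES:
            raise ValidationError(
                f"row {idx}: category {row.category!r} not in {sorted(ARTS_CATEGORIES)}"
            )
        records.append(
            ArtsHit(
                bgc_id=ensure_prefix(row.bgc_id, NS_BGC),
                profile_id=ensure_prefix(row.profile_id, NS_ARTS),
                category=row.category,
            )
        )
    return records


_SCHEMA_READERS = {
    "bgcs": _read_bgcs,
    "edges": _read_edges,
    "kcb_hits": _read_kcb_hits,
    "bigfam_membership": _read_bigfam_membership,
    "bigfam_genus_counts": _read_genus_counts,
    "arts_hits": _read_arts_hits,
}


def write_table(records: Iterable, path, schema: str) -> None:
    """Write typed records back to canonical TSV (inverse of read_table)."""
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    cols = SCHEMAS[schema]
    rows = []
    for rec in records:
        row = {f.name: getattr(rec, f.name) for f in dc_fields(rec)}
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(cols))
    if schema == "bgcs" and len(frame):
        frame["on_contig_edge"] = frame["on_contig_edge"].map(
            lambda v: "true" if v else "false"
        )
    frame.to_csv(path, sep="\t", index=False)


def read_distance_matrix(path) -> DistanceMatrix:
    """Read a square MASH-style distance TSV with id header row and column."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    ids = tuple(str(i) for i in frame.index)
    cols = tuple(str(c) for c in frame.columns)
    if ids != cols:
        raise ValidationError("distance matrix row and column ids differ")
    return DistanceMatrix(ids=ids, values=frame.to_numpy(dtype=float))


def write_distance_matrix(d: DistanceMatrix, path) -> None:
    frame = pd.DataFrame(d.values, index=list(d.ids), columns=list(d.ids))
    frame.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Graph export

GRAPH_FORMATS = ("graphml", "tsv")


def write_graph(graph: nx.Graph, path, format: str = "graphml") -> list[Path]:
    """Write a typed heterogeneous graph to disk.

    ``graphml`` emits a single GraphML file; ``tsv`` emits a paired
    ``<stem>.nodes.tsv`` / ``<stem>.edges.tsv``. Node ids are preserved
    verbatim, including namespace prefixes.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(graph, path)
        return [path]
    if format == "tsv":
        stem = path.with_suffix("") if path.suffix == ".tsv" else path
        nodes_path = stem.with_name(stem.name + ".nodes.tsv")
        edges_path = stem.with_name(stem.name + ".edges.tsv")
        node_rows = []
        for node, data in sorted(graph.nodes(data=True)):
            row = {"node_id": node}
            row.update(data)
            node_rows.append(row)
        node_frame = pd.DataFrame(node_rows)
        if "node_type" not in node_frame.columns:
            node_frame["node_type"] = pd.Series(dtype=str)
        node_frame.to_csv(nodes_path, sep="\t", index=False)
        edge_rows = []
        for a, b, data in sorted(graph.edges(data=True), key=lambda e: (e[0], e[1])):
            row = {"source": a, "target": b}
            row.update(data)
            edge_rows.append(row)
        edge_frame = pd.DataFrame(edge_rows)
        for col in ("edge_type", "weight"):
            if col not in edge_frame.columns:
                edge_frame[col] = pd.Series(dtype=float)
        edge_frame.to_csv(edges_path, sep="\t", index=False)
        return [nodes_path, edges_path]
    raise UsageError(f"unknown graph format {format!r}; one of {GRAPH_FORMATS}")


def read_graph(path, format: str = "graphml") -> nx.Graph:
    """Read a graph written by :func:`write_graph`."""
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "tsv":
        stem = path.with_suffix("") if path.suffix == ".tsv" else path
        nodes_path = stem.with_name(stem.name + ".nodes.tsv")
        edges_path = stem.with_name(stem.name + ".edges.tsv")
        graph = nx.Graph()
        nodes = pd.read_csv(nodes_path, sep="\t", dtype=str)
        for _, row in nodes.iterrows():
            attrs = {
                k: v for k, v in row.items() if k != "node_id" and pd.notna(v)
            }
            graph.add_node(row["node_id"], **attrs)
        edges = pd.read_csv(edges_path, sep="\t", dtype=str)
        for _, row in edges.iterrows():
            attrs = {
                k: v
                for k, v in row.items()
                if k not in ("source", "target") and pd.notna(v)
            }
            if "weight" in attrs:
                attrs["weight"] = float(attrs["weight"])
            graph.add_edge(row["source"], row["target"], **attrs)
        return graph
    raise UsageError(f"unknown graph format {format!r}; one of {GRAPH_FORMATS}")
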