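"""Readers, writers and graph/metric construction for the pipeline's file formats.

The pipeline consumes four kinds of external input, all plain text:

* an undirected protein--protein interaction network as a two-column edge list;
* pathway gene sets in GMT format (name, description, then genes, tab-separated);
* per-cancer mutation tables in a minimal MAF dialect (tab-separated with a
  header; only ``Hugo_Symbol`` and ``Tumor_Sample_Barcode`` are required);
* known-driver catalogs as one-symbol-per-line gene lists.

Gene symbols from every source are normalized identically (whitespace-stripped,
uppercased) so joins across files are by normalized symbol.  Graphs are simple
``networkx.Graph`` objects with unit edge weights by default; the metric space
used downstream is the all-pairs shortest-path matrix with ``+inf`` between
different connected components.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

logger = logging.getLogger("phimpact")

__all__ = [
    "ParseError",
    "MutationTable",
    "PathwayGeneSet",
    "DriverCatalog",
    "DistanceMatrix",
    "normalize_symbol",
    "graph_from_edges",
    "read_edge_list",
    "write_edge_list",
    "read_gene_sets",
    "write_gene_sets",
    "read_mutation_table",
    "write_mutation_table",
    "read_driver_catalog",
    "write_driver_list",
    "induced_subgraph",
    "shortest_path_matrix",
]


class ParseError(ValueError):
    """Raised when an input file violates its dialect."""


def normalize_symbol(symbol: str) -> str:
    """Strip whitespace and uppercase a gene symbol.

    Raises ``ValueError`` for symbols that are empty after stripping.
    """
    s = symbol.strip().upper()
    if not s:
        raise ValueError("empty gene symbol")
    return s


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationTable:
    """Set of (sample id, gene symbol) pairs for one cancer type."""

    label: str
    records: frozenset[tuple[str, str]]

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for _, g in self.records)

    @property
    def samples(self) -> frozenset[str]:
        return frozenset(s for s, _ in self.records)


@dataclass(frozen=True)
class PathwayGeneSet:
    """A named pathway gene set (one GMT line)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass(frozen=True)
class DriverCatalog:
    """Union of known-driver gene lists with per-gene source provenance."""

    sources: Mapping[str, frozenset[str]]  # gene -> labels of files listing it

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.sources)

    def __contains__(self, gene: str) -> bool:
        return gene in self.sources


@dataclass(frozen=True)
class DistanceMatrix:
    """All-pairs shortest-path distances over a fixed (sorted) node order.

    ``values[i, j]`` is the hop-count (or weighted) shortest-path length
    between ``nodes[i]`` and ``nodes[j]``; ``+inf`` marks pairs in different
    connected components.
    """

    nodes: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.nodes)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        finite = np.isfinite(v)
        if not np.array_equal(finite, finite.T) or not np.allclose(
            v[finite], v.T[finite]
        ):
            raise ValueError("distance matrix must be symmetric")

    def __len__(self) -> int:
        return len(self.nodes)

    def d(self, u: str, v: str) -> float:
        i, j = self.nodes.index(u), self.nodes.index(v)
        return float(self.values[i, j])

    @property
    def diameter(self) -> float:
        """Largest finite entry (max within-component eccentricity)."""
        finite = self.values[np.isfinite(self.values)]
        return float(finite.max()) if finite.size else 0.0

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.nodes, columns=self.nodes)
        df.to_csv(path, na_rep="inf")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        values = df.to_numpy(dtype=float)
        values[~np.isfinite(values)] = math.inf
        return cls(nodes=tuple(str(c) for c in df.columns), values=values)


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------


def graph_from_edges(
    edges: Iterable[tuple[str, str] | tuple[str, str, float]],
    nodes: Iterable[str] = (),
) -> nx.Graph:
    """Build a simple undirected graph from (u, v[, weight]) tuples.

    Symbols are normalized; self-loops are dropped with a warning; duplicate
    edges are collapsed keeping the first weight seen.  Extra ``nodes`` are
    added as isolated vertices.
    """
    g = nx.Graph()
    for node in nodes:
        g.add_node(normalize_symbol(node))
    for edge in edges:
        u, v = normalize_symbol(edge[0]), normalize_symbol(edge[1])
        w = float(edge[2]) if len(edge) > 2 else 1.0
        if w <= 0:
            raise ValueError(f"non-positive edge weight {w} on ({u}, {v})")
        if u == v:
            logger.warning("dropping self-loop on node %s", u)
            g.add_node(u)
            continue
        if not g.has_edge(u, v):  # keep first weight on duplicates
            g.add_edge(u, v, weight=w)
        else:
            g.add_node(u), g.add_node(v)
    return g


def read_edge_list(path: str | Path, delimiter: str | None = None) -> nx.Graph:
    """Read an undirected edge list (two symbol columns, optional weight).

    Lines starting with ``#`` and blank lines are skipped.  ``delimiter=None``
    splits on any whitespace.
    """
    path = Path(path)
    edges: list[tuple[str, str, float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected >=2 columns, got {len(parts)}")
            try:
                weight = float(parts[2]) if len(parts) > 2 else 1.0
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
            edges.append((parts[0], parts[1], weight))
    if not edges:
        raise ParseError(f"{path}: no edges found")
    return graph_from_edges(edges)


def write_edge_list(
    g: nx.Graph, path: str | Path, delimiter: str = "\t", header: Sequence[str] = ()
) -> None:
    """Write a graph as an edge list.

    Isolated nodes are emitted as self-loop lines ``N<TAB>N``: the reader
    drops the loop but keeps the node, so round-trips preserve the node set.
    """
    with Path(path).open("w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for node in sorted(nx.isolates(g)):
            fh.write(f"{node}{delimiter}{node}\n")
        for u, v, data in sorted(g.edges(data=True)):
            w = data.get("weight", 1.0)
            if w == 1.0:
                fh.write(f"{u}{delimiter}{v}\n")
            else:
                fh.write(f"{u}{delimiter}{v}{delimiter}{w}\n")


def read_gene_sets(path: str | Path) -> list[PathwayGeneSet]:
    """Read pathway gene sets from a GMT file (name, description, genes...)."""
    path = Path(path)
    sets: list[PathwayGeneSet] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            genes = frozenset(normalize_symbol(f) for f in fields[2:] if f.strip())
            sets.append(PathwayGeneSet(name=fields[0].strip(), genes=genes))
    return sets


def write_gene_sets(sets: Iterable[PathwayGeneSet], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *sorted(gs.genes)]) + "\n")


def read_mutation_table(
    path: str | Path, label: str, nonsilent_only: bool = False
) -> MutationTable:
    """Read a MAF-dialect TSV into a (sample, gene) record set.

    Only ``Hugo_Symbol`` and ``Tumor_Sample_Barcode`` are used; with
    ``nonsilent_only`` rows whose ``Variant_Classification`` equals ``Silent``
    are dropped (that column is then required).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("Hugo_Symbol", "Tumor_Sample_Barcode"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if nonsilent_only:
        if "Variant_Classification" not in df.columns:
            raise ParseError(
                f"{path}: nonsilent_only requires column 'Variant_Classification'"
            )
        df = df[df["Variant_Classification"].str.strip() != "Silent"]
    if df.empty:
        logger.warning("%s: mutation table %s has no usable rows", path, label)
        return MutationTable(label=label, records=frozenset())
    records = frozenset(
        (str(s).strip(), normalize_symbol(g))
        for s, g in zip(df["Tumor_Sample_Barcode"], df["Hugo_Symbol"])
    )
    return MutationTable(label=label, records=records)


def write_mutation_table(table: MutationTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\n")
        for sample, gene in sorted(table.records, key=lambda r: (r[1], r[0])):
            fh.write(f"{gene}\t{sample}\tMissense_Mutation\n")


def read_driver_catalog(paths: Sequence[str | Path]) -> DriverCatalog:
    """Union one-symbol-per-line gene lists into a catalog with provenance."""
    sources: dict[str, set[str]] = {}
    total = 0
    for path in paths:
        path = Path(path)
        label = path.stem
        with path.open() as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                sources.setdefault(normalize_symbol(line), set()).add(label)
                total += 1
    if total == 0:
        raise ParseError(f"no genes found in driver lists: {[str(p) for p in paths]}")
    return DriverCatalog(
        sources={g: frozenset(labels) for g, labels in sources.items()}
    )


def write_driver_list(genes: Iterable[str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for gene in sorted(genes):
            fh.write(gene + "\n")


# ---------------------------------------------------------------------------
# graph -> metric space
# ---------------------------------------------------------------------------


def induced_subgraph(g: nx.Graph, genes: Iterable[str]) -> nx.Graph:
    """Induced subgraph on ``g.nodes & genes``; isolated nodes are retained.

    Genes absent from the graph are ignored (their count is logged); an empty
    intersection yields an empty graph with a warning, not an error.
    """
    wanted = {normalize_symbol(s) for s in genes}
    kept = wanted & set(g.nodes)
    missing = len(wanted) - len(kept)
    if missing:
        logger.info("induced_subgraph: %d requested genes absent from graph", missing)
    if not kept:
        logger.warning("induced_subgraph: empty intersection, returning empty graph")
    return nx.Graph(g.subgraph(kept))


def shortest_path_matrix(g: nx.Graph, weighted: bool = False) -> DistanceMatrix:
    """All-pairs shortest paths over sorted node order.

    Hop counts (BFS) by default; with ``weighted=True`` Dijkstra over the
    ``weight`` attribute.  Pairs in different components get ``+inf``.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot build a distance matrix for an empty graph")
    nodes = tuple(sorted(g.nodes))
    adj = nx.to_scipy_sparse_array(g, nodelist=nodes, weight="weight", format="csr")
    values = _csgraph_shortest_path(
        adj, method="D", directed=False, unweighted=not weighted
    )
    values = np.asarray(values, dtype=float)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(nodes=nodes, values=values)
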