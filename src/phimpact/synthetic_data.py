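"""Synthetic fixtures: polyhedral graphs, planted-void networks, mutation studies.

Everything the pipeline consumes can be generated here deterministically from
a seed, so the full consensus -> CCN -> persistence -> impact chain is
testable without any external download:

* the five Platonic polyhedral skeletons, whose Vietoris--Rips barcodes over
  hop distances are known closed-form fixtures;
* planted-void networks -- a triangle-free background graph (random tree plus
  long chords) with octahedral gadgets attached by single cut vertices.  The
  octahedron is the minimal VR-realizable 2-sphere (a hollow 4-clique fills
  into a solid simplex under VR, so 4-vertex "voids" cannot exist), and the
  construction guarantees provable ground truth at filtration scale 1: each
  gadget contributes exactly one void, every gadget vertex has removal delta
  -1, and every background vertex has delta 0;
* synthetic multi-cancer mutation studies with planted recurrent genes
  (support >= k by construction) and sporadic genes (support < k), plus a
  driver catalog drawn from the recurrent set.

Generated objects write themselves in the same text dialects the readers in
:mod:`phimpact.network_io` parse, so synthetic studies exercise the real
parsers end to end.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .network_io import (
    DriverCatalog,
    MutationTable,
    shortest_path_matrix,
    write_driver_list,
    write_mutation_table,
)
from .vr_persistence import homology_rank_oracle

logger = logging.getLogger("phimpact")

__all__ = [
    "POLYHEDRA",
    "PlantedTruth",
    "SyntheticStudy",
    "make_polyhedron",
    "make_planted_void_network",
    "make_fused_octahedra",
    "make_synthetic_study",
]

POLYHEDRA = ("tetrahedron", "cube", "octahedron", "dodecahedron", "icosahedron")

_POLY_BUILDERS = {
    "tetrahedron": nx.tetrahedral_graph,
    "cube": nx.cubical_graph,
    "octahedron": nx.octahedral_graph,
    "dodecahedron": nx.dodecahedral_graph,
    "icosahedron": nx.icosahedral_graph,
}

_CANCER_LABELS = ("BLADDER", "BREAST", "HEADNECK", "LUNG", "SKIN", "STOMACH")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for a planted-void network.

    ``expected_delta`` maps every node to the B2 change its removal causes at
    filtration scale ``scale`` (the clique-complex scale, where the
    construction makes the deltas provable).
    """

    void_vertices: frozenset[str]
    background_vertices: frozenset[str]
    expected_delta: Mapping[str, int]
    n_voids: int
    scale: float = 1.0


@dataclass(frozen=True)
class SyntheticStudy:
    """A multi-cancer mutation study with known recurrent/sporadic genes."""

    tables: tuple[MutationTable, ...]
    recurrent_genes: frozenset[str]
    sporadic_genes: frozenset[str]
    catalog: DriverCatalog
    min_cancers: int
    seed: int

    def write_to(self, directory: str | Path) -> dict[str, list[Path]]:
        """Materialize MAF files and the driver list; returns written paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        maf_paths: list[Path] = []
        for table in self.tables:
            p = directory / f"{table.label.lower()}.maf.tsv"
            write_mutation_table(table, p)
            maf_paths.append(p)
        driver_path = directory / "drivers.txt"
        write_driver_list(self.catalog.genes, driver_path)
        return {"maf": maf_paths, "drivers": [driver_path]}


def make_polyhedron(name: str) -> nx.Graph:
    """The named Platonic skeleton with unit weights and deterministic labels.

    Nodes are labeled ``<PREFIX><index>`` (e.g. ``DOD00`` .. ``DOD19``).
    """
    try:
        builder = _POLY_BUILDERS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown polyhedron {name!r}; choose from {POLYHEDRA}")
    g = builder()
    prefix = name[:3].upper()
    mapping = {n: f"{prefix}{int(n):02d}" for n in g.nodes}
    out = nx.relabel_nodes(g, mapping)
    nx.set_edge_attributes(out, 1.0, "weight")
    return out


def _octahedron_gadget(tag: str) -> nx.Graph:
    """A relabeled octahedron with vertices ``<tag>A`` .. ``<tag>F``."""
    g = nx.octahedral_graph()
    mapping = dict(zip(sorted(g.nodes), string.ascii_uppercase))
    out = nx.relabel_nodes(g, {n: f"{tag}{mapping[n]}" for n in g.nodes})
    nx.set_edge_attributes(out, 1.0, "weight")
    return out


def _random_triangle_free_background(
    n: int, rng: np.random.Generator
) -> nx.Graph:
    """Random tree on ``BG``-labeled nodes plus chords between nodes at
    distance >= 3, so the background stays triangle-free (no 2-simplices at
    scale 1, hence no void contribution)."""
    g = nx.Graph()
    labels = [f"BG{i:03d}" for i in range(n)]
    g.add_nodes_from(labels)
    for i in range(1, n):
        j = int(rng.integers(0, i))
        g.add_edge(labels[i], labels[j], weight=1.0)
    n_chords = n // 5
    attempts = 0
    added = 0
    while added < n_chords and attempts < 20 * n_chords:
        attempts += 1
        u, v = (labels[int(k)] for k in rng.choice(n, size=2, replace=False))
        if g.has_edge(u, v):
            continue
        try:
            if nx.shortest_path_length(g, u, v) < 3:
                continue
        except nx.NetworkXNoPath:
            pass
        g.add_edge(u, v, weight=1.0)
        added += 1
    return g


def make_planted_void_network(
    n_background: int,
    n_voids: int,
    attach: str = "bridge",
    seed: int = 0,
) -> tuple[nx.Graph, PlantedTruth]:
    """A background graph with octahedral void gadgets attached by cut vertices.

    ``attach="bridge"`` joins each gadget to the rest of the network by a
    single bridge edge; ``attach="shared"`` merges one gadget vertex into a
    background node (that node then carries the gadget's -1 delta).  Either
    way no triangle spans the attachment, so at scale 1 the clique complex is
    the background (1-dimensional) wedged with ``n_voids`` octahedral
    2-spheres, and the ground truth deltas are exact.

    For instances of at most 12 vertices the claimed void count is verified
    against the rank--nullity oracle at generation time.
    """
    if n_voids < 1:
        raise ValueError(f"n_voids must be >= 1, got {n_voids}")
    if n_background < 0:
        raise ValueError(f"n_background must be >= 0, got {n_background}")
    if attach not in ("bridge", "shared"):
        raise ValueError(f"attach must be 'bridge' or 'shared', got {attach!r}")
    if attach == "shared" and n_background == 0 and n_voids > 1:
        raise ValueError("shared attachment needs a background to merge into")
    rng = np.random.default_rng(seed)

    g = _random_triangle_free_background(n_background, rng)
    background = frozenset(g.nodes)
    expected: dict[str, int] = {node: 0 for node in background}
    void_vertices: set[str] = set()

    anchors_pool = sorted(background)
    prev_gadget_anchor: str | None = None
    for gi in range(n_voids):
        gadget = _octahedron_gadget(f"VOID{gi}")
        gadget_nodes = sorted(gadget.nodes)
        if attach == "shared" and anchors_pool:
            anchor = anchors_pool[int(rng.integers(0, len(anchors_pool)))]
            anchors_pool.remove(anchor)  # distinct anchors keep deltas -1
            merged = gadget_nodes[0]
            gadget = nx.relabel_nodes(gadget, {merged: anchor})
            g = nx.compose(g, gadget)
            for node in gadget.nodes:
                expected[node] = expected.get(node, 0) - 1
                void_vertices.add(node)
        else:
            g = nx.compose(g, gadget)
            for node in gadget_nodes:
                expected[node] = -1
                void_vertices.add(node)
            if anchors_pool:
                anchor = anchors_pool[int(rng.integers(0, len(anchors_pool)))]
                g.add_edge(anchor, gadget_nodes[0], weight=1.0)
            elif prev_gadget_anchor is not None:
                g.add_edge(prev_gadget_anchor, gadget_nodes[0], weight=1.0)
            prev_gadget_anchor = gadget_nodes[-1]

    truth = PlantedTruth(
        void_vertices=frozenset(void_vertices),
        background_vertices=background - frozenset(void_vertices),
        expected_delta=expected,
        n_voids=n_voids,
        scale=1.0,
    )
    if g.number_of_nodes() <= 12:
        found = homology_rank_oracle(shortest_path_matrix(g), truth.scale, 2)
        if found != n_voids:
            raise AssertionError(
                f"generator self-check failed: oracle B2={found}, planted {n_voids}"
            )
    logger.info(
        "planted-void network: %d nodes, %d voids, %d background",
        g.number_of_nodes(), n_voids, len(truth.background_vertices),
    )
    return g, truth


def make_fused_octahedra(n_gadgets: int = 2) -> tuple[nx.Graph, PlantedTruth]:
    """``n_gadgets`` octahedra sharing one common vertex.

    The shared vertex participates in every 2-sphere, so its removal delta is
    ``-n_gadgets``; every other gadget vertex has delta -1.
    """
    if n_gadgets < 1:
        raise ValueError("need at least one gadget")
    shared = "HUB"
    g = nx.Graph()
    expected: dict[str, int] = {}
    for gi in range(n_gadgets):
        gadget = _octahedron_gadget(f"VOID{gi}")
        first = sorted(gadget.nodes)[0]
        gadget = nx.relabel_nodes(gadget, {first: shared})
        g = nx.compose(g, gadget)
        for node in gadget.nodes:
            if node != shared:
                expected[node] = -1
    expected[shared] = -n_gadgets
    truth = PlantedTruth(
        void_vertices=frozenset(expected),
        background_vertices=frozenset(),
        expected_delta=expected,
        n_voids=n_gadgets,
        scale=1.0,
    )
    if g.number_of_nodes() <= 12:
        found = homology_rank_oracle(shortest_path_matrix(g), truth.scale, 2)
        if found != n_gadgets:
            raise AssertionError(
                f"generator self-check failed: oracle B2={found}, planted {n_gadgets}"
            )
    return g, truth


def make_synthetic_study(
    n_cancers: int = 6,
    min_cancers: int = 4,
    n_recurrent: int = 10,
    n_sporadic: int = 30,
    samples_per_cancer: int = 50,
    driver_fraction: float = 0.5,
    seed: int = 0,
    recurrent_genes: Sequence[str] | None = None,
    sporadic_genes: Sequence[str] | None = None,
) -> SyntheticStudy:
    """Generate per-cancer mutation tables with planted recurrence structure.

    Recurrent genes are assigned to between ``min_cancers`` and ``n_cancers``
    randomly chosen cancer types; sporadic genes to fewer than ``min_cancers``.
    Consensus selection at threshold ``min_cancers`` therefore recovers
    exactly the recurrent set.  Gene names default to ``RGENE*``/``SGENE*``
    but can be overridden (e.g. with the vertices of a planted-void network)
    to build end-to-end studies.
    """
    if not (1 <= min_cancers <= n_cancers):
        raise ValueError(
            f"need 1 <= min_cancers <= n_cancers, got {min_cancers}, {n_cancers}"
        )
    if not (0.0 <= driver_fraction <= 1.0):
        raise ValueError(f"driver_fraction must be in [0, 1]: {driver_fraction}")
    if samples_per_cancer < 1:
        raise ValueError("samples_per_cancer must be >= 1")
    rng = np.random.default_rng(seed)

    if recurrent_genes is None:
        recurrent = [f"RGENE{i:03d}" for i in range(n_recurrent)]
    else:
        recurrent = sorted(dict.fromkeys(recurrent_genes))
    if sporadic_genes is None:
        sporadic = [f"SGENE{i:03d}" for i in range(n_sporadic)]
    else:
        sporadic = sorted(dict.fromkeys(sporadic_genes))
    if set(recurrent) & set(sporadic):
        raise ValueError("recurrent and sporadic gene sets overlap")

    labels = [
        _CANCER_LABELS[i] if i < len(_CANCER_LABELS) else f"CANCER{i}"
        for i in range(n_cancers)
    ]
    assignments: dict[str, list[int]] = {}
    for gene in recurrent:
        support = int(rng.integers(min_cancers, n_cancers + 1))
        assignments[gene] = sorted(
            int(c) for c in rng.choice(n_cancers, size=support, replace=False)
        )
    for gene in sporadic:
        support = int(rng.integers(1, min_cancers)) if min_cancers > 1 else 0
        assignments[gene] = sorted(
            int(c) for c in rng.choice(n_cancers, size=support, replace=False)
        )

    records: list[set[tuple[str, str]]] = [set() for _ in range(n_cancers)]
    for gene in recurrent + sporadic:
        for ci in assignments[gene]:
            n_hits = int(rng.integers(1, min(4, samples_per_cancer) + 1))
            samples = rng.choice(samples_per_cancer, size=n_hits, replace=False)
            for s in samples:
                records[ci].add((f"{labels[ci]}-S{int(s):03d}", gene))

    tables = tuple(
        MutationTable(label=labels[ci], records=frozenset(records[ci]))
        for ci in range(n_cancers)
    )
    n_drivers = round(driver_fraction * len(recurrent))
    drivers = sorted(
        str(g) for g in rng.choice(recurrent, size=n_drivers, replace=False)
    ) if n_drivers else []
    catalog = DriverCatalog(
        sources={g: frozenset({"synthetic"}) for g in drivers}
    )
    return SyntheticStudy(
        tables=tables,
        recurrent_genes=frozenset(recurrent),
        sporadic_genes=frozenset(g for g in sporadic if assignments[g]),
        catalog=catalog,
        min_cancers=min_cancers,
        seed=seed,
    )
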