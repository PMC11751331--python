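"""Consensus gene lists across cancer types and consensus-network construction.

A gene enters the consensus list when it is mutated (in at least one sample)
in at least ``min_cancers`` of the supplied per-cancer mutation tables --
presence semantics, so a gene counts once per cancer type no matter how many
samples carry it.  A Cancer Consensus Network (CCN) is then the induced
subgraph of a Super Pathway Network (SPN) on the consensus genes, annotated
with known-driver membership and per-gene support counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .network_io import DriverCatalog, MutationTable, induced_subgraph

logger = logging.getLogger("phimpact")

__all__ = [
    "ConsensusConfig",
    "ConsensusList",
    "AnnotatedNetwork",
    "build_consensus_list",
    "build_ccn",
    "write_consensus_csv",
]


@dataclass(frozen=True)
class ConsensusConfig:
    """Recurrence threshold: keep genes mutated in >= ``min_cancers`` types."""

    min_cancers: int = 4
    n_cancers: int | None = None

    def __post_init__(self) -> None:
        if self.min_cancers < 1:
            raise ValueError(f"min_cancers must be >= 1, got {self.min_cancers}")


@dataclass(frozen=True)
class ConsensusList:
    """Genes passing the recurrence threshold, with per-gene support counts."""

    support: Mapping[str, int]  # gene -> number of cancer types it appears in
    min_cancers: int
    n_cancers: int

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.support)


@dataclass(frozen=True)
class AnnotatedNetwork:
    """A CCN: graph plus per-node driver flags, support counts and retention."""

    graph: nx.Graph
    driver_flags: Mapping[str, bool]
    support: Mapping[str, int]
    spn_nodes: int
    spn_drivers: int

    @property
    def node_retention(self) -> float | None:
        if self.spn_nodes == 0:
            return None
        return self.graph.number_of_nodes() / self.spn_nodes

    @property
    def driver_retention(self) -> float | None:
        if self.spn_drivers == 0:
            return None
        kept = sum(1 for v in self.driver_flags.values() if v)
        return kept / self.spn_drivers

    @property
    def drivers(self) -> frozenset[str]:
        return frozenset(g for g, flag in self.driver_flags.items() if flag)


def build_consensus_list(
    tables: Sequence[MutationTable], config: ConsensusConfig | None = None
) -> ConsensusList:
    """Select genes mutated in at least ``config.min_cancers`` distinct tables.

    Support counts are returned for every included gene.  ``min_cancers``
    above the number of tables is a configuration error.
    """
    config = config or ConsensusConfig()
    if not tables:
        raise ValueError("at least one mutation table is required")
    k = config.min_cancers
    if k > len(tables):
        raise ValueError(
            f"min_cancers={k} exceeds the {len(tables)} mutation tables supplied"
        )
    counts: dict[str, int] = {}
    for table in tables:
        for gene in table.genes:
            counts[gene] = counts.get(gene, 0) + 1
    support = {g: c for g, c in sorted(counts.items()) if c >= k}
    logger.info(
        "consensus: %d/%d genes mutated in >=%d of %d cancer types",
        len(support), len(counts), k, len(tables),
    )
    return ConsensusList(support=support, min_cancers=k, n_cancers=len(tables))


def build_ccn(
    spn: nx.Graph, consensus: ConsensusList, catalog: DriverCatalog
) -> AnnotatedNetwork:
    """Induce the CCN from an SPN on the consensus genes and flag drivers."""
    if spn.number_of_nodes() == 0:
        raise ValueError("SPN is empty")
    graph = induced_subgraph(spn, consensus.genes)
    if graph.number_of_nodes() == 0:
        logger.warning("CCN is empty: no consensus gene appears in the SPN")
    spn_drivers = sum(1 for n in spn.nodes if n in catalog)
    net = AnnotatedNetwork(
        graph=graph,
        driver_flags={n: n in catalog for n in sorted(graph.nodes)},
        support={n: consensus.support[n] for n in sorted(graph.nodes)},
        spn_nodes=spn.number_of_nodes(),
        spn_drivers=spn_drivers,
    )
    if net.node_retention is not None:
        logger.info(
            "CCN: %d/%d SPN nodes retained (%.0f%%), %d/%d drivers",
            graph.number_of_nodes(), net.spn_nodes, 100 * net.node_retention,
            len(net.drivers), spn_drivers,
        )
    return net


def write_consensus_csv(
    consensus: ConsensusList,
    catalog: DriverCatalog,
    path: str | Path,
    header: Sequence[str] = (),
) -> None:
    """CSV columns: gene, support_count, is_known_driver."""
    with Path(path).open("w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("gene,support_count,is_known_driver\n")
        for gene in sorted(consensus.genes):
            fh.write(f"{gene},{consensus.support[gene]},{gene in catalog}\n")
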