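"""Classical centrality measures and percentile positioning of gene sets.

Four node-level measures, all normalized to [0, 1]:

* degree centrality ``deg(v) / (n - 1)``;
* local clustering coefficient;
* betweenness centrality (endpoints excluded, ``2 / ((n-1)(n-2))``
  normalization);
* closeness with the Wasserman--Faust component scaling
  ``(n_comp - 1) / (n - 1)``, so values stay comparable on disconnected
  networks.

``rank_positions`` places a set of genes (typically the impactful ones)
within each measure's distribution as percentile ranks with mean ranks for
ties, mapping the minimum to 0 and the maximum to 100.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "MEASURES",
    "centrality_table",
    "rank_positions",
    "write_centrality_csv",
    "plot_centrality_strip",
]

MEASURES = ("degree", "clustering", "betweenness", "closeness")


def centrality_table(g: nx.Graph, normalized: bool = True) -> pd.DataFrame:
    """Per-node degree/clustering/betweenness/closeness as a DataFrame.

    With ``normalized=False``, degree and betweenness are raw counts and
    closeness drops the component scaling (clustering is scale-free either
    way).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("centrality on an empty graph")
    table = pd.DataFrame(
        {
            "degree": dict(g.degree())
            if not normalized
            else nx.degree_centrality(g),
            "clustering": nx.clustering(g),
            "betweenness": nx.betweenness_centrality(g, normalized=normalized),
            "closeness": nx.closeness_centrality(g, wf_improved=normalized),
        }
    )
    if g.number_of_nodes() == 1:  # degree_centrality divides by n-1
        table["degree"] = 0.0
    return table.sort_index()


def rank_positions(
    profile: pd.DataFrame, genes: Iterable[str]
) -> pd.DataFrame:
    """Percentile rank of each listed gene per measure, mean rank for ties.

    Percentile = ``(mean_rank - 1) / (n - 1) * 100``: a unique maximum sits
    at 100, a unique minimum at 0, and a fully tied column at 50.
    """
    genes = sorted(set(genes))
    unknown = [g for g in genes if g not in profile.index]
    if unknown:
        raise KeyError(f"genes absent from centrality profile: {unknown}")
    n = len(profile)
    ranks = profile.rank(method="average")
    pct = ranks * 0.0 + 50.0 if n == 1 else (ranks - 1.0) / (n - 1.0) * 100.0
    return pct.loc[genes]


def write_centrality_csv(
    profile: pd.DataFrame,
    path: str | Path,
    impact_class: Mapping[str, str] | None = None,
    header: Sequence[str] = (),
) -> None:
    """CSV columns: gene, the four measures, and optional impact_class."""
    out = profile.copy()
    out.index.name = "gene"
    if impact_class is not None:
        out["impact_class"] = [
            impact_class.get(g, "non-impactful") for g in out.index
        ]
    with Path(path).open("w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        out.to_csv(fh)


def plot_centrality_strip(
    profile: pd.DataFrame,
    highlight: Mapping[str, str] | None = None,
    path: str | Path | None = None,
):
    """Strip plot of the four centrality distributions with highlighted genes.

    ``highlight`` maps gene -> color; remaining genes are drawn grey.  A
    convenience for visual inspection, not part of the numeric pipeline.
    Requires matplotlib; returns the figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    highlight = dict(highlight or {})
    fig, axes = plt.subplots(1, len(MEASURES), figsize=(3 * len(MEASURES), 4))
    for ax, measure in zip(axes, MEASURES):
        base = profile.drop(index=list(highlight), errors="ignore")
        ax.scatter([0] * len(base), base[measure], s=12, c="0.7", zorder=1)
        for gene, color in highlight.items():
            if gene in profile.index:
                ax.scatter([0], [profile.loc[gene, measure]], s=30, c=color, zorder=2)
        ax.set_title(measure)
        ax.set_xticks([])
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
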