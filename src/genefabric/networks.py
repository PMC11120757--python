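"""Significant-coordination networks and their remodeling between conditions.

Nodes are the genes of a set; an edge is stored only for classified pairs —
synergistic (both genes' expression fluctuating in phase across replicas),
antagonistic (in anti-phase) or independent (correlation inside the
independence band, suggesting no direct interaction). A missing edge means
the correlation was not statistically significant. Comparing two
conditions' networks yields the edges gained, lost and flipped
(synergism <-> antagonism), the classic signature of pathway remodeling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .characteristics import (
    ANTAGONISTIC,
    INDEPENDENT,
    SYNERGISTIC,
    ALPHA,
    IND_THRESHOLD,
    SYN_THRESHOLD,
    pair_correlations,
)
from .io import ExpressionSet

__all__ = ["NetworkDiff", "build_network", "annotate_regulation", "compare_networks",
           "network_edge_frame", "write_graphml", "plot_network"]


def build_network(
    eset: ExpressionSet,
    gene_set: Sequence[str] | None = None,
    *,
    alpha: float = ALPHA,
    syn_threshold: float = SYN_THRESHOLD,
    ind_threshold: float = IND_THRESHOLD,
) -> nx.Graph:
    """Coordination network of one condition over a gene set.

    Every gene of the set quantified in the expression set becomes a node;
    classified pairs become undirected edges with ``class`` and ``COR``
    attributes. Unclassified pairs are omitted.
    """
    data = eset.data if gene_set is None else eset.data.loc[eset.data.index.intersection(pd.Index(gene_set))]
    if len(data) < 2:
        raise ValueError("a coordination network needs at least 2 quantified genes")
    edges = pair_correlations(
        data,
        alpha=alpha,
        syn_threshold=syn_threshold,
        ind_threshold=ind_threshold,
        classified_only=True,
    )
    graph = nx.Graph(condition=eset.condition)
    graph.add_nodes_from(data.index)
    for row in edges.itertuples(index=False):
        graph.add_edge(
            row.gene_i,
            row.gene_j,
            **{"cor": float(row.COR), "p": float(row.p), "class": getattr(row, "_4")},
        )
    return graph


def annotate_regulation(graph: nx.Graph, status: Mapping[str, str] | pd.Series) -> nx.Graph:
    """Attach regulation status (up/down/not-regulated) as node attributes."""
    status = pd.Series(status)
    for node in graph.nodes:
        if node in status.index:
            graph.nodes[node]["status"] = status[node]
    return graph


@dataclass
class NetworkDiff:
    """Remodeling of the coordination network between two conditions.

    ``gained``/``lost`` are classified pairs present in only one condition;
    ``flipped`` are pairs switching between synergism and antagonism;
    ``reclassified`` covers the remaining class changes (to or from
    independence). ``degree_change`` is the per-gene change in the number of
    significant (synergistic + antagonistic) partners, condition b minus a.
    """

    condition_a: str
    condition_b: str
    gained: frozenset[frozenset]
    lost: frozenset[frozenset]
    flipped: frozenset[frozenset]
    reclassified: frozenset[frozenset]
    degree_change: pd.Series

    @property
    def n_gained(self) -> int:
        return len(self.gained)

    @property
    def n_lost(self) -> int:
        return len(self.lost)

    @property
    def n_flipped(self) -> int:
        return len(self.flipped)

    def is_empty(self) -> bool:
        return not (self.gained or self.lost or self.flipped or self.reclassified) and (
            self.degree_change == 0
        ).all()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kind, pairs in (
            ("gained", self.gained),
            ("lost", self.lost),
            ("flipped", self.flipped),
            ("reclassified", self.reclassified),
        ):
            for pair in sorted(pairs, key=sorted):
                u, v = sorted(pair)
                rows.append({"gene_i": u, "gene_j": v, "change": kind})
        return pd.DataFrame(rows, columns=["gene_i", "gene_j", "change"])


def _edge_classes(graph: nx.Graph) -> dict[frozenset, str]:
    return {frozenset((u, v)): d["class"] for u, v, d in graph.edges(data=True)}


def _significant_degree(graph: nx.Graph) -> pd.Series:
    deg = {n: 0 for n in graph.nodes}
    for u, v, d in graph.edges(data=True):
        if d["class"] in (SYNERGISTIC, ANTAGONISTIC):
            deg[u] += 1
            deg[v] += 1
    return pd.Series(deg)


def compare_networks(graph_a: nx.Graph, graph_b: nx.Graph) -> NetworkDiff:
    """Edge-level remodeling from condition a to condition b (same gene set)."""
    if set(graph_a.nodes) != set(graph_b.nodes):
        raise ValueError("networks to compare must share the same gene set")
    ea = _edge_classes(graph_a)
    eb = _edge_classes(graph_b)
    gained = frozenset(eb.keys() - ea.keys())
    lost = frozenset(ea.keys() - eb.keys())
    flipped = set()
    reclassified = set()
    for pair in ea.keys() & eb.keys():
        ca, cb = ea[pair], eb[pair]
        if ca == cb:
            continue
        if {ca, cb} == {SYNERGISTIC, ANTAGONISTIC}:
            flipped.add(pair)
        else:
            reclassified.add(pair)
    degree_change = (_significant_degree(graph_b) - _significant_degree(graph_a)).sort_index()
    return NetworkDiff(
        condition_a=graph_a.graph.get("condition", "a"),
        condition_b=graph_b.graph.get("condition", "b"),
        gained=gained,
        lost=lost,
        flipped=frozenset(flipped),
        reclassified=frozenset(reclassified),
        degree_change=degree_change,
    )


def network_edge_frame(graph: nx.Graph) -> pd.DataFrame:
    rows = [
        {"gene_i": u, "gene_j": v, "class": d["class"], "COR": d["cor"], "p": d["p"]}
        for u, v, d in graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["gene_i", "gene_j", "class", "COR", "p"])


def write_graphml(graph: nx.Graph, path: str | Path) -> Path:
    path = Path(path)
    nx.write_graphml(graph, path)
    return path


_EDGE_STYLE = {SYNERGISTIC: ("red", "solid"), ANTAGONISTIC: ("blue", "solid"), INDEPENDENT: ("black", "dashed")}
_NODE_COLOR = {"up": "lightcoral", "down": "lightgreen", "not-regulated": "khaki"}


def plot_network(graph: nx.Graph, path: str | Path, *, seed: int = 0) -> Path:
    """Static plot: edge style by coordination class, node color by regulation."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = nx.spring_layout(graph, seed=seed)
    fig, ax = plt.subplots(figsize=(8, 8))
    node_colors = [_NODE_COLOR.get(graph.nodes[n].get("status", ""), "lightgray") for n in graph.nodes]
    nx.draw_networkx_nodes(graph, pos, node_color=node_colors, ax=ax, node_size=600)
    nx.draw_networkx_labels(graph, pos, ax=ax, font_size=7)
    for cls, (color, style) in _EDGE_STYLE.items():
        edges = [(u, v) for u, v, d in graph.edges(data=True) if d["class"] == cls]
        nx.draw_networkx_edges(graph, pos, edgelist=edges, edge_color=color, style=style, ax=ax)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
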