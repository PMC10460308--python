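"""Weighted-network centrality indices used to rank substances.

Local indices summarise a node's direct connections: strength is the sum of
absolute edge weights, expected influence the signed sum.  Global indices
use geodesics with edge length ``1/|weight|``: closeness is the inverse of
the total distance to (reachable) nodes, betweenness the number of shortest
paths passing through a node, splitting ties fractionally.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .zero_order import WeightedNetwork

__all__ = ["CentralityProfile", "centrality_indices", "rank_substances"]

INDICES = ("strength", "expected_influence", "closeness", "betweenness")


@dataclass
class CentralityProfile:
    table: pd.DataFrame  # index = node labels; raw and z-scored columns
    disconnected: bool  # True when closeness was computed within components

    def __getitem__(self, index: str) -> pd.Series:
        return self.table[index]


def _zscore(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return x * 0.0
    return (x - x.mean()) / sd


def centrality_indices(net: WeightedNetwork, use_mask: bool = True) -> CentralityProfile:
    """Compute strength, expected influence, closeness and betweenness.

    ``use_mask=True`` restricts to displayed edges (absent edges carry no
    weight and infinite length).  Closeness on a disconnected network sums
    distances over reachable nodes only and is flagged.
    """
    W = net.displayed_weights() if use_mask else net.weights.copy()
    np.fill_diagonal(W, 0.0)
    if not np.isfinite(W).all():
        raise ValueError("centrality requires finite edge weights")
    if np.all(W == 0):
        raise ValueError("all edge weights are zero; geodesics are undefined")
    labels = net.labels
    strength = np.abs(W).sum(axis=1)
    expected_influence = W.sum(axis=1)

    G = nx.Graph()
    G.add_nodes_from(range(len(labels)))
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if W[i, j] != 0:
                G.add_edge(i, j, length=1.0 / abs(W[i, j]))
    closeness = np.zeros(len(labels))
    disconnected = not nx.is_connected(G)
    for i in G.nodes:
        dist = nx.single_source_dijkstra_path_length(G, i, weight="length")
        total = sum(d for node, d in dist.items() if node != i)
        closeness[i] = 1.0 / total if total > 0 else 0.0
    betweenness_dict = nx.betweenness_centrality(G, weight="length", normalized=False)
    betweenness = np.array([betweenness_dict[i] for i in range(len(labels))])

    table = pd.DataFrame(
        {
            "strength": strength,
            "expected_influence": expected_influence,
            "closeness": closeness,
            "betweenness": betweenness,
        },
        index=pd.Index(labels, name="node"),
    )
    for idx in INDICES:
        table[f"{idx}_z"] = _zscore(table[idx])
    return CentralityProfile(table=table, disconnected=disconnected)


def rank_substances(profile: CentralityProfile) -> dict:
    """Rank nodes per index (descending, lexicographic tie-break).

    Returns ``{"ranking": {index: [node, ...]}, "ties": {index: [...]},
    "top_on_majority": [...]}`` where the last lists nodes top-ranked on at
    least three of the four indices.
    """
    ranking: dict[str, list[str]] = {}
    ties: dict[str, list[str]] = {}
    for idx in INDICES:
        s = profile.table[idx]
        order = sorted(s.index, key=lambda node: (-s[node], node))
        ranking[idx] = order
        tied = [
            node
            for node in s.index
            if (np.isclose(s[node], s.drop(node)).any())
        ]
        ties[idx] = sorted(tied)
    top_counts: dict[str, int] = {}
    for idx in INDICES:
        top_counts[ranking[idx][0]] = top_counts.get(ranking[idx][0], 0) + 1
    top_on_majority = sorted(n for n, c in top_counts.items() if c >= 3)
    return {"ranking": ranking, "ties": ties, "top_on_majority": top_on_majority}
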