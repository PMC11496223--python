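"""Protein-protein interaction network construction and MCC hub scoring.

MCC (maximal clique centrality) scores a node v as the sum of
(|C| - 1)! over all maximal cliques C containing v with |C| >= 2.  A
degree-1 node's only maximal clique is its edge, contributing 1! = 1;
isolated nodes score 0 by default (flag-switchable to 1).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = ["PPINetwork", "HubScores", "build_network", "mcc_scores"]


@dataclass
class PPINetwork:
    graph: nx.Graph
    threshold: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class HubScores:
    scores: pd.Series  # node -> MCC, descending

    def top(self, k: int) -> list[str]:
        return list(self.scores.index[:k])


def build_network(
    edges: pd.DataFrame,
    threshold: float = 0.4,
    restrict_to: list[str] | None = None,
) -> PPINetwork:
    """Build an undirected confidence-thresholded PPI network.

    ``edges`` needs columns node_a, node_b, score (in [0, 1]).  Edges
    below ``threshold`` and self-loops are dropped; duplicate edges
    collapse to one canonical undirected edge (highest score wins).  With
    ``restrict_to``, the induced subgraph on those genes is returned and
    listed genes without any retained edge stay as degree-0 nodes.
    """
    required = {"node_a", "node_b", "score"}
    if not required <= set(edges.columns):
        raise ValueError(f"edge table must have columns {sorted(required)}")
    g = nx.Graph()
    for i, row in enumerate(edges.itertuples(index=False)):
        a, b, s = str(row.node_a), str(row.node_b), float(row.score)
        if not 0 <= s <= 1:
            raise ValueError(f"row {i}: score {s} outside [0, 1]")
        if a == b:
            continue
        if s < threshold:
            continue
        if g.has_edge(a, b):
            g[a][b]["score"] = max(g[a][b]["score"], s)
        else:
            g.add_edge(a, b, score=s)
    if restrict_to is not None:
        keep = set(restrict_to)
        g = g.subgraph(keep & set(g.nodes)).copy()
        g.add_nodes_from(keep - set(g.nodes))
    return PPINetwork(graph=g, threshold=threshold)


def mcc_scores(
    network: PPINetwork,
    isolated_score: int = 0,
    max_nodes: int = 5000,
) -> HubScores:
    """Maximal clique centrality for every node.

    Maximal cliques come from the Bron-Kerbosch enumeration in networkx;
    scoring is exponential worst-case, hence the node-count guard.
    Ties in the ranking break alphabetically for determinism.
    """
    g = network.graph
    if g.number_of_nodes() > max_nodes:
        raise ValueError(
            f"network has {g.number_of_nodes()} nodes (> {max_nodes}); "
            "restrict to a query gene list first"
        )
    scores = {v: 0 for v in g.nodes}
    for clique in nx.find_cliques(g):
        if len(clique) < 2:
            continue
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += contrib
    for v, s in scores.items():
        if s == 0 and g.degree(v) == 0:
            scores[v] = isolated_score
    ser = pd.Series(scores, name="mcc").sort_index()
    ser = ser.sort_values(ascending=False, kind="stable")
    return HubScores(scores=ser)
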