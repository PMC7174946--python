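"""Node-topology metric suite and hub ranking for interaction networks.

Metric conventions follow Cytoscape's NetworkAnalyzer: every metric is
computed within the node's connected component, closeness is the
reciprocal of the mean shortest-path length, betweenness is normalized
by (n−1)(n−2)/2 with n the component size, radiality rescales the mean
path length by the component diameter, and the topological coefficient
averages shared-neighbor overlap over all partners sharing a neighbor.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

METRIC_COLUMNS = [
    "node",
    "degree",
    "avg_shortest_path",
    "betweenness",
    "closeness",
    "clustering_coef",
    "neighborhood_connectivity",
    "radiality",
    "topological_coef",
]


class GraphInputError(ValueError):
    """Malformed edge-list input."""


def build_graph(edges) -> nx.Graph:
    """Undirected simple graph from 2- or 3-column records.

    Accepts an iterable of (u, v) or (u, v, score) rows or a DataFrame
    whose first three columns are so interpreted. Self-loops are
    dropped and duplicate edges collapsed (last score wins).
    """
    graph = nx.Graph()
    if isinstance(edges, pd.DataFrame):
        edges = edges.itertuples(index=False)
    for lineno, row in enumerate(edges, start=1):
        row = tuple(row)
        if len(row) not in (2, 3):
            raise GraphInputError(f"row {lineno}: expected 2 or 3 columns, got {len(row)}")
        u, v = row[0], row[1]
        if u == v:
            continue
        if len(row) == 3:
            try:
                score = float(row[2])
            except (TypeError, ValueError) as exc:
                raise GraphInputError(f"row {lineno}: bad score {row[2]!r}") from exc
            graph.add_edge(u, v, score=score)
        else:
            graph.add_edge(u, v)
    return graph


def _topological_coefficient(graph: nx.Graph, node) -> float:
    k = graph.degree(node)
    if k <= 1:
        return 0.0
    neighbors = set(graph[node])
    partners = {}
    for w in neighbors:
        for u in graph[w]:
            if u == node:
                continue
            partners[u] = partners.get(u, 0) + 1
    if not partners:
        return 0.0
    total = 0.0
    for u, shared in partners.items():
        j = shared + (1 if graph.has_edge(node, u) else 0)
        total += j
    return total / (len(partners) * k)


def topology_metrics(graph: nx.Graph) -> pd.DataFrame:
    """Per-node metric vector, one row per node, within components.

    Isolated nodes report 0 for every path-based metric; degree-1 nodes
    have topological coefficient 0 by convention.
    """
    rows = {n: {"node": n, "degree": graph.degree(n)} for n in graph.nodes}
    clustering = nx.clustering(graph)
    for comp_nodes in nx.connected_components(graph):
        comp = graph.subgraph(comp_nodes)
        n = comp.number_of_nodes()
        if n >= 2:
            spl = dict(nx.all_pairs_shortest_path_length(comp))
            diameter = max(max(d.values()) for d in spl.values())
            betw = nx.betweenness_centrality(comp, normalized=True)
        else:
            spl, diameter, betw = {}, 0, {}
        for node in comp_nodes:
            row = rows[node]
            if n >= 2:
                dists = [d for t, d in spl[node].items() if t != node]
                mean_l = sum(dists) / len(dists)
                row["avg_shortest_path"] = mean_l
                row["closeness"] = 1.0 / mean_l
                row["betweenness"] = betw[node]
                row["radiality"] = (diameter + 1.0 - mean_l) / diameter if diameter > 0 else 0.0
            else:
                row["avg_shortest_path"] = 0.0
                row["closeness"] = 0.0
                row["betweenness"] = 0.0
                row["radiality"] = 0.0
            row["clustering_coef"] = clustering[node]
            degs = [graph.degree(w) for w in graph[node]]
            row["neighborhood_connectivity"] = sum(degs) / len(degs) if degs else 0.0
            row["topological_coef"] = _topological_coefficient(graph, node)
    out = pd.DataFrame(list(rows.values()), columns=METRIC_COLUMNS)
    return out.sort_values("node", kind="stable").reset_index(drop=True)


def hub_ranking(metrics: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Top-k nodes by degree (descending), ties broken by node id.

    ``k`` larger than the node count returns all nodes; k ≤ 0 returns an
    empty table with the same schema.
    """
    if k <= 0:
        return metrics.iloc[0:0].copy()
    ordered = metrics.sort_values(
        ["degree", "node"], ascending=[False, True], kind="stable"
    )
    return ordered.head(k).reset_index(drop=True)
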