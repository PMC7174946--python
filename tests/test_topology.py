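"""Graph construction and the node-topology metric suite."""

from collections import deque
from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cernapipe import topology


def brute_force_metrics(g: nx.Graph) -> dict:
    """Exhaustive oracle: BFS distances, simple-path betweenness, direct formulas."""
    nodes = list(g.nodes)
    dist = {}
    for s in nodes:
        d = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for w in g[u]:
                if w not in d:
                    d[w] = d[u] + 1
                    queue.append(w)
        dist[s] = d

    def all_shortest_paths(s, t):
        best = dist[s].get(t)
        found = []
        stack = [[s]]
        while stack:
            path = stack.pop()
            u = path[-1]
            if len(path) - 1 > best:
                continue
            if u == t and len(path) - 1 == best:
                found.append(path)
                continue
            for w in g[u]:
                if w not in path and dist[s].get(w) == len(path) - 1 + 1:
                    stack.append(path + [w])
        return found

    out = {}
    for v in nodes:
        comp = {u for u in nodes if u in dist[v]}
        n = len(comp)
        deg = g.degree(v)
        if n >= 2:
            dists = [dist[v][u] for u in comp if u != v]
            mean_l = sum(dists) / len(dists)
            diameter = max(dist[a][b] for a in comp for b in comp)
            betw = 0.0
            for s, t in permutations(sorted(comp), 2):
                if s == v or t == v or dist[s].get(t) is None:
                    continue
                paths = all_shortest_paths(s, t)
                betw += sum(1 for p in paths if v in p[1:-1]) / len(paths)
            betw /= 2  # each unordered pair counted twice
            norm = (n - 1) * (n - 2) / 2
            betw = betw / norm if norm > 0 else 0.0
            radiality = (diameter + 1 - mean_l) / diameter if diameter > 0 else 0.0
            closeness = 1 / mean_l
        else:
            mean_l = betw = radiality = closeness = 0.0
        neigh = list(g[v])
        nc = sum(g.degree(w) for w in neigh) / len(neigh) if neigh else 0.0
        if deg >= 2:
            links = sum(1 for a in neigh for b in neigh if a < b and g.has_edge(a, b))
            cc = 2 * links / (deg * (deg - 1))
        else:
            cc = 0.0
        if deg <= 1:
            tc = 0.0
        else:
            partners = {}
            for w in neigh:
                for u in g[w]:
                    if u != v:
                        partners[u] = partners.get(u, 0) + 1
            if partners:
                tc = sum(j + (1 if g.has_edge(v, u) else 0)
                         for u, j in partners.items()) / (len(partners) * deg)
            else:
                tc = 0.0
        out[v] = {"degree": deg, "avg_shortest_path": mean_l, "betweenness": betw,
                  "closeness": closeness, "clustering_coef": cc,
                  "neighborhood_connectivity": nc, "radiality": radiality,
                  "topological_coef": tc}
    return out


class TestBuildGraph:
    def test_self_loops_and_duplicates_collapsed(self):
        g = topology.build_graph([("a", "b"), ("b", "a"), ("a", "a")])
        assert g.number_of_edges() == 1 and g.number_of_nodes() == 2

    def test_empty_input_gives_empty_graph(self):
        g = topology.build_graph([])
        assert g.number_of_nodes() == 0

    def test_scored_edges_round_trip(self, tmp_path):
        df = pd.DataFrame({"node1": ["a", "b"], "node2": ["b", "c"], "score": [0.9, 0.5]})
        path = tmp_path / "edges.tsv"
        df.to_csv(path, sep="\t", index=False)
        g = topology.build_graph(pd.read_csv(path, sep="\t"))
        assert g["a"]["b"]["score"] == 0.9 and g["b"]["c"]["score"] == 0.5

    def test_malformed_row_reports_line(self):
        with pytest.raises(topology.GraphInputError, match="row 2"):
            topology.build_graph([("a", "b"), ("c",)])


class TestTopologyMetrics:
    def test_three_node_path_closed_form(self):
        m = topology.topology_metrics(topology.build_graph([("a", "b"), ("b", "c")]))
        m = m.set_index("node")
        assert m.loc["b", "betweenness"] == 1.0
        assert m.loc["b", "closeness"] == 1.0
        assert m.loc["b", "avg_shortest_path"] == 1.0
        assert m.loc["a", "betweenness"] == 0.0

    def test_triangle_closed_form(self):
        m = topology.topology_metrics(nx.complete_graph(3))
        assert (m["clustering_coef"] == 1.0).all()
        assert (m["betweenness"] == 0.0).all()

    def test_star_closed_form(self):
        m = topology.topology_metrics(nx.star_graph(5)).set_index("node")
        assert m.loc[0, "degree"] == 5
        assert m.loc[1, "neighborhood_connectivity"] == 5.0
        assert m.loc[0, "radiality"] == 1.0

    def test_matches_brute_force_on_random_graphs(self, rng):
        cols = topology.METRIC_COLUMNS[1:]
        for i in range(100):
            n = int(rng.integers(2, 9))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.9)), seed=int(rng.integers(1e6)))
            got = topology.topology_metrics(g).set_index("node")
            want = brute_force_metrics(g)
            for v in g.nodes:
                for col in cols:
                    assert got.loc[v, col] == pytest.approx(want[v][col], abs=1e-12), (
                        f"graph {i}, node {v}, metric {col}")

    def test_degree_sum_and_closeness_identity(self, rng):
        g = nx.gnp_random_graph(12, 0.3, seed=4)
        m = topology.topology_metrics(g)
        assert m["degree"].sum() == 2 * g.number_of_edges()
        in_comp = m[m["avg_shortest_path"] > 0]
        assert np.allclose(in_comp["closeness"] * in_comp["avg_shortest_path"], 1.0)

    def test_invariant_under_relabeling(self, rng):
        g = nx.gnp_random_graph(8, 0.4, seed=9)
        mapping = {i: f"n{i}" for i in g.nodes}
        m1 = topology.topology_metrics(g).set_index("node")
        m2 = topology.topology_metrics(nx.relabel_nodes(g, mapping)).set_index("node")
        for i in g.nodes:
            for col in topology.METRIC_COLUMNS[1:]:
                assert m1.loc[i, col] == pytest.approx(m2.loc[f"n{i}", col])

    def test_leaf_betweenness_zero(self, rng):
        g = nx.random_labeled_tree(10, seed=2)
        m = topology.topology_metrics(g).set_index("node")
        for v in g.nodes:
            if g.degree(v) == 1:
                assert m.loc[v, "betweenness"] == 0.0


class TestHubRanking:
    def test_star_center_first(self):
        m = topology.topology_metrics(nx.star_graph(4))
        assert topology.hub_ranking(m, k=1).loc[0, "node"] == 0

    def test_k_beyond_node_count_returns_all(self):
        m = topology.topology_metrics(nx.path_graph(3))
        assert len(topology.hub_ranking(m, k=10)) == 3

    def test_nonpositive_k_empty(self):
        m = topology.topology_metrics(nx.path_graph(3))
        assert len(topology.hub_ranking(m, k=0)) == 0

    def test_degree_descending_with_id_tiebreak(self):
        g = topology.build_graph([("a", "b"), ("c", "b"), ("a", "c"), ("d", "a")])
        out = topology.hub_ranking(topology.topology_metrics(g), k=4)
        assert list(out["node"]) == ["a", "b", "c", "d"]
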