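"""Graph metrics against trivial cases and independent oracles.

networkx and scipy.sparse.csgraph serve as the reference implementations;
for tiny graphs betweenness is additionally checked against exhaustive
simple-path enumeration, which shares no code with the Brandes routine.
"""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import floyd_warshall

from pcnkit import build_pcn
from pcnkit.metrics import (betweenness, closeness, clustering_coefficient,
                            degree, eccentricity, global_summary, metric_table,
                            shortest_paths, zscore_select)

from conftest import network_from_edges, random_gnp_edges


def triangle():
    return network_from_edges(3, [(0, 1), (1, 2), (0, 2)])


def path(n):
    return network_from_edges(n, [(i, i + 1) for i in range(n - 1)])


def star(leaves):
    return network_from_edges(leaves + 1, [(0, i) for i in range(1, leaves + 1)])


class TestTrivialGraphs:
    def test_triangle_degrees_and_clustering(self):
        net = triangle()
        assert list(degree(net)) == [2, 2, 2]
        assert list(clustering_coefficient(net)) == [1.0, 1.0, 1.0]

    def test_star_center_and_leaves(self):
        net = star(4)
        assert list(degree(net)) == [4, 1, 1, 1, 1]
        assert clustering_coefficient(net).iloc[0] == 0.0

    def test_path3_betweenness(self):
        bc = betweenness(path(3))
        assert list(bc) == [0.0, 1.0, 0.0]

    def test_complete_graph_betweenness_zero(self):
        net = network_from_edges(5, itertools.combinations(range(5), 2))
        assert np.allclose(betweenness(net), 0.0)

    def test_k4_closeness_symmetric(self):
        net = network_from_edges(4, itertools.combinations(range(4), 2))
        assert closeness(net).nunique() == 1

    def test_path3_closeness_middle_largest(self):
        c = closeness(path(3))
        assert c.iloc[1] > c.iloc[0] == c.iloc[2]

    def test_path4_distance(self):
        sp = shortest_paths(path(4))
        assert sp[0, 3] == 3

    def test_disconnected_pair_is_infinite_and_excluded_from_L(self):
        net = network_from_edges(4, [(0, 1), (2, 3)])
        sp = shortest_paths(net)
        assert np.isinf(sp[0, 2])
        assert global_summary(net)["characteristic_path_length"] == 1.0

    def test_degree_one_node_has_zero_betweenness(self):
        net = network_from_edges(6, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 1), (1, 5)])
        assert betweenness(net).iloc[5] == 0.0


def brute_force_betweenness(n, edges):
    """Count shortest paths by exhaustive simple-path enumeration (n <= 7)."""
    adj = {i: set() for i in range(n)}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    def all_paths(s, t):
        paths = []
        stack = [(s, [s])]
        while stack:
            v, p = stack.pop()
            if v == t:
                paths.append(p)
                continue
            for w in adj[v]:
                if w not in p:
                    stack.append((w, p + [w]))
        return paths

    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        d = min(len(p) for p in paths)
        shortest = [p for p in paths if len(p) == d]
        for p in shortest:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(shortest)
    return bc


class TestOracles:
    @pytest.mark.parametrize("seed", range(20))
    def test_betweenness_vs_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        edges = random_gnp_edges(n, 0.5, rng)
        net = network_from_edges(n, edges)
        assert np.allclose(betweenness(net).values,
                           brute_force_betweenness(n, edges), atol=1e-9)

    @pytest.mark.parametrize("seed", range(40))
    def test_all_metrics_vs_networkx(self, seed):
        """Random G(n,p) graphs, n in [5, 50]: every metric matches networkx
        and every distance matrix matches Floyd-Warshall."""
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(5, 51))
        p = float(rng.uniform(0.05, 0.4))
        edges = random_gnp_edges(n, p, rng)
        net = network_from_edges(n, edges)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(edges)

        assert list(degree(net)) == [g.degree[i] for i in range(n)]
        assert np.allclose(clustering_coefficient(net).values,
                           [nx.clustering(g, i) for i in range(n)])
        bc_nx = nx.betweenness_centrality(g, normalized=False)
        assert np.allclose(betweenness(net).values, [bc_nx[i] for i in range(n)])
        bc_norm = nx.betweenness_centrality(g, normalized=True)
        assert np.allclose(betweenness(net, normalized=True).values,
                           [bc_norm[i] for i in range(n)])
        cl_nx = nx.closeness_centrality(g, wf_improved=False)
        assert np.allclose(closeness(net).values, [cl_nx[i] for i in range(n)])
        sp = shortest_paths(net)
        fw = floyd_warshall(net.adjacency.astype(float), unweighted=True)
        assert np.array_equal(sp, fw)

    @pytest.mark.parametrize("seed", range(5))
    def test_handshake_identity(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        net = network_from_edges(n, random_gnp_edges(n, 0.3, rng))
        assert degree(net).sum() == 2 * net.n_edges


class TestZScoreSelection:
    def test_constant_series_selects_nothing(self):
        s = metric_table(triangle())["degree"]
        with pytest.warns(UserWarning):
            sel = zscore_select(s, 1.0, "degree")
        assert len(sel.selected) == 0

    def test_hand_computed_outlier(self):
        import pandas as pd
        s = pd.Series([0.0, 0.0, 0.0, 10.0], index=[1, 2, 3, 4])
        sel = zscore_select(s, 1.0)
        assert list(sel.selected.index) == [4]
        assert sel.selected.iloc[0] == pytest.approx(1.732, abs=1e-3)

    def test_selection_is_strictly_above_threshold(self):
        import pandas as pd
        s = pd.Series([1.0, 2.0, 3.0, 4.0])
        sel = zscore_select(s, float(((s - s.mean()) / s.std(ddof=0)).max()))
        assert len(sel.selected) == 0


def test_metric_table_on_real_fixture(mixed_chain):
    net = build_pcn(mixed_chain)
    t = metric_table(net)
    assert set(t.columns) == {"degree", "clustering", "betweenness",
                              "closeness", "eccentricity"}
    assert t["clustering"].between(0, 1).all()
    assert (t["betweenness"] >= 0).all()
    assert t["degree"].sum() == 2 * net.n_edges
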