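"""TOM, shortest paths, Dj scoring and network descriptives.

Independent oracles: naive triple-loop TOM, hand-written Floyd-Warshall,
direct per-node evaluation of the Dj formula, and brute-force degree /
betweenness enumeration on tiny graphs.
"""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from degnet import network as net


def random_weighted_graph(seed, n_max=20, p=0.35):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, n_max + 1))
    g = nx.Graph()
    g.add_nodes_from(f"n{i:02d}" for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(f"n{i:02d}", f"n{j:02d}",
                           weight=float(rng.uniform(0.05, 1.0)))
    return g


def naive_tom(g):
    nodes = sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    n = len(nodes)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            denom = min(ki, kj) + 1.0 - a[i, j]
            tom[i, j] = (l + a[i, j]) / denom if denom > 0 else 0.0
    return pd.DataFrame(tom, index=nodes, columns=nodes)


def floyd_warshall(dist):
    sp = dist.copy().astype(float)
    n = sp.shape[0]
    np.fill_diagonal(sp, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                via = sp[i, k] + sp[k, j]
                if via < sp[i, j]:
                    sp[i, j] = via
    return sp


def naive_dj(sp, core):
    nodes = list(sp.index)
    c = sum(n in core for n in nodes)
    nc = len(nodes) - c
    out = {}
    for j in nodes:
        s_core = sum(sp.loc[i, j] for i in nodes if i in core)
        s_non = sum(sp.loc[i, j] for i in nodes if i not in core)
        denom = (s_core + s_non) / (c + nc)
        out[j] = 0.0 if denom == 0 else (s_non / nc - s_core / c) / denom
    return pd.Series(out)


class TestBuildGraph:
    def test_triangle(self):
        edges = pd.DataFrame({"node_a": ["A", "B", "A"],
                              "node_b": ["B", "C", "C"],
                              "weight": [0.5, 0.6, 0.7]})
        g = net.build_graph(edges)
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 3
        assert g["A"]["B"]["weight"] == 0.5

    def test_zero_weight_edge_dropped_with_warning(self):
        edges = pd.DataFrame({"node_a": ["A", "B"], "node_b": ["B", "C"],
                              "weight": [0.0, 0.4]})
        with pytest.warns(UserWarning):
            g = net.build_graph(edges)
        assert not g.has_edge("A", "B")

    def test_weight_above_one_rejected(self):
        edges = pd.DataFrame({"node_a": ["A"], "node_b": ["B"],
                              "weight": [1.2]})
        with pytest.raises(ValueError):
            net.build_graph(edges)


class TestGiantComponent:
    def test_connected_graph_returned_whole(self):
        g = nx.path_graph(4)
        assert set(net.giant_component(g).nodes) == set(g.nodes)

    def test_largest_component_wins(self):
        g = nx.Graph()
        g.add_edges_from([("A", "B"), ("B", "C"), ("X", "Y")])
        assert set(net.giant_component(g).nodes) == {"A", "B", "C"}

    def test_size_tie_breaks_to_smallest_member(self):
        g = nx.Graph()
        g.add_edges_from([("B", "C"), ("C", "D"), ("A", "X"), ("X", "Z")])
        assert "A" in net.giant_component(g).nodes

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            net.giant_component(nx.Graph())


class TestTOM:
    def test_isolated_pair_hand_value(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=0.5)
        tom = net.tom_similarity(g)
        assert tom.loc["A", "B"] == pytest.approx(0.5)

    def test_unit_triangle_is_one(self):
        g = nx.Graph()
        g.add_weighted_edges_from([("A", "B", 1.0), ("B", "C", 1.0),
                                   ("A", "C", 1.0)])
        tom = net.tom_similarity(g)
        assert tom.loc["A", "B"] == pytest.approx(1.0)

    def test_no_edge_no_shared_neighbor_is_zero(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=0.5)
        g.add_edge("C", "D", weight=0.5)
        tom = net.tom_similarity(g)
        assert tom.loc["A", "C"] == 0.0

    def test_unweighted_complete_graph_all_ones(self):
        g = nx.complete_graph(6)
        nx.set_edge_attributes(g, 1.0, "weight")
        tom = net.tom_similarity(g).to_numpy()
        assert np.allclose(tom, 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_triple_loop(self, seed):
        g = random_weighted_graph(seed)
        vec = net.tom_similarity(g)
        ref = naive_tom(g)
        assert np.abs(vec.to_numpy() - ref.to_numpy()).max() < 1e-10

    def test_non_adjacent_shared_neighbor_pairs_positive(self):
        g = nx.Graph()
        g.add_edge("A", "M", weight=0.8)
        g.add_edge("M", "B", weight=0.9)
        tom = net.tom_similarity(g)
        assert tom.loc["A", "B"] > 0

    def test_weight_out_of_range_rejected(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=1.5)
        with pytest.raises(ValueError):
            net.tom_similarity(g)


class TestTomDistance:
    def test_complement_with_zero_diagonal(self):
        g = random_weighted_graph(3)
        tom = net.tom_similarity(g)
        dist = net.tom_distance(tom)
        assert (np.diag(dist.to_numpy()) == 0).all()
        off = ~np.eye(len(dist), dtype=bool)
        np.testing.assert_allclose(dist.to_numpy()[off],
                                   (1.0 - tom.to_numpy())[off])
        assert ((dist.to_numpy() >= 0) & (dist.to_numpy() <= 1)).all()
        assert np.allclose(dist.to_numpy(), dist.to_numpy().T)


class TestShortestPaths:
    def test_two_node_direct_distance(self):
        dist = pd.DataFrame([[0.0, 0.3], [0.3, 0.0]],
                            index=["A", "B"], columns=["A", "B"])
        sp = net.shortest_path_matrix(dist)
        assert sp.loc["A", "B"] == pytest.approx(0.3)

    def test_two_hop_relaxation(self):
        nodes = ["A", "B", "C"]
        dist = pd.DataFrame([[0.0, 0.3, 0.9],
                             [0.3, 0.0, 0.3],
                             [0.9, 0.3, 0.0]], index=nodes, columns=nodes)
        sp = net.shortest_path_matrix(dist)
        assert sp.loc["A", "C"] == pytest.approx(0.6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_floyd_warshall_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        d = rng.uniform(0.0, 1.0, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        nodes = [f"n{i}" for i in range(n)]
        frame = pd.DataFrame(d, index=nodes, columns=nodes)
        sp = net.shortest_path_matrix(frame)
        assert np.abs(sp.to_numpy() - floyd_warshall(d)).max() < 1e-12

    def test_complete_mode_bounded_by_direct_distance(self):
        g = random_weighted_graph(11)
        dist = net.tom_distance(net.tom_similarity(g))
        sp = net.shortest_path_matrix(dist)
        assert (sp.to_numpy() <= dist.to_numpy() + 1e-12).all()
        assert (sp.to_numpy() <= 1.0 + 1e-12).all()

    def test_edges_only_mode_respects_graph(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=0.9)
        g.add_edge("B", "C", weight=0.9)
        dist = net.tom_distance(net.tom_similarity(g))
        sp = net.shortest_path_matrix(dist, mode="edges_only", graph=g)
        # A-C has no edge: must go through B even if the complete-mode
        # matrix offers a direct step
        expected = dist.loc["A", "B"] + dist.loc["B", "C"]
        assert sp.loc["A", "C"] == pytest.approx(expected)

    def test_negative_distance_rejected(self):
        dist = pd.DataFrame([[0.0, -0.1], [-0.1, 0.0]],
                            index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ValueError):
            net.shortest_path_matrix(dist)


class TestDjScores:
    def _sp_from_unweighted(self, g):
        nodes = sorted(g.nodes)
        sp = dict(nx.all_pairs_shortest_path_length(g))
        m = np.array([[sp[i][j] for j in nodes] for i in nodes], float)
        return pd.DataFrame(m, index=nodes, columns=nodes)

    def test_symmetric_four_cycle_scores_zero(self):
        g = nx.cycle_graph(["A", "B", "C", "D"])
        sp = self._sp_from_unweighted(g)
        scores = net.dj_scores(sp, {"A", "C"})
        assert scores.loc["B", "dj"] == pytest.approx(0.0, abs=1e-12)
        assert scores.loc["D", "dj"] == pytest.approx(0.0, abs=1e-12)

    def test_three_node_path_hand_value(self):
        g = nx.path_graph(["A", "j", "B"])
        sp = self._sp_from_unweighted(g)
        scores = net.dj_scores(sp, {"A"})
        assert scores.loc["j", "dj"] == pytest.approx(-0.75)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_formula(self, seed):
        g = random_weighted_graph(seed + 50, n_max=12, p=0.5)
        g = net.giant_component(g)
        if g.number_of_nodes() < 4:
            pytest.skip("degenerate random instance")
        sp = net.shortest_path_matrix(net.tom_distance(net.tom_similarity(g)))
        core = set(sorted(g.nodes)[:2])
        scores = net.dj_scores(sp, core)
        ref = naive_dj(sp, core)
        assert np.abs(scores["dj"] - ref[scores.index]).max() < 1e-12

    def test_label_swap_flips_numerator_sign(self):
        g = net.giant_component(random_weighted_graph(60, n_max=10, p=0.6))
        sp = net.shortest_path_matrix(net.tom_distance(net.tom_similarity(g)))
        nodes = sorted(g.nodes)
        core = set(nodes[: len(nodes) // 2])
        rest = set(nodes) - core
        a = net.dj_scores(sp, core)
        b = net.dj_scores(sp, rest)
        m = sp.to_numpy(float)
        denom = m.sum(axis=0) / len(nodes)
        num_a = a["dj"].to_numpy() * denom
        num_b = b["dj"].to_numpy() * denom
        np.testing.assert_allclose(num_a, -num_b, atol=1e-12)

    def test_core_validation(self):
        sp = pd.DataFrame(np.zeros((2, 2)), index=["A", "B"],
                          columns=["A", "B"])
        with pytest.raises(ValueError):
            net.dj_scores(sp, set())
        with pytest.raises(ValueError):
            net.dj_scores(sp, {"A", "B"})
        with pytest.raises(ValueError):
            net.dj_scores(sp, {"Z"})


class TestExtractCoreNetwork:
    def _scores(self, g, dj, core):
        return pd.DataFrame({"dj": [dj[n] for n in g.nodes],
                             "is_core": [n in core for n in g.nodes]},
                            index=list(g.nodes))

    def test_only_cores_kept_when_all_scores_negative(self):
        g = nx.path_graph(["A", "B", "C"])
        nx.set_edge_attributes(g, 0.5, "weight")
        scores = self._scores(g, {"A": 0.5, "B": -0.1, "C": -0.2}, {"A"})
        sub = net.extract_core_network(g, scores)
        assert set(sub.nodes) == {"A"}

    def test_zero_score_excluded_strictly(self):
        g = nx.path_graph(["A", "B", "C"])
        nx.set_edge_attributes(g, 0.5, "weight")
        scores = self._scores(g, {"A": 0.5, "B": 0.0, "C": 0.1}, {"A"})
        sub = net.extract_core_network(g, scores)
        assert set(sub.nodes) == {"A", "C"}

    def test_attributes_attached(self):
        g = nx.path_graph(["A", "B"])
        nx.set_edge_attributes(g, 0.5, "weight")
        scores = self._scores(g, {"A": 0.4, "B": 0.2}, {"A"})
        sub = net.extract_core_network(g, scores)
        assert sub.nodes["A"]["is_core"] and not sub.nodes["B"]["is_core"]
        assert sub.nodes["B"]["dj"] == pytest.approx(0.2)


class TestNetworkDescriptives:
    def test_triangle(self):
        g = nx.complete_graph(["A", "B", "C"])
        nx.set_edge_attributes(g, 1.0, "weight")
        d = net.network_descriptives(g)
        assert d["transitivity"] == pytest.approx(1.0)
        assert d["density"] == pytest.approx(1.0)
        assert d["diameter"] == 1

    def test_three_node_path(self):
        g = nx.path_graph(["A", "B", "C"])
        nx.set_edge_attributes(g, 0.8, "weight")
        d = net.network_descriptives(g)
        assert d["transitivity"] == 0.0
        assert d["density"] == pytest.approx(2 / 3)
        assert d["diameter"] == 2
        assert d["mean_distance"] == pytest.approx(4 / 3)

    @pytest.mark.parametrize("seed", range(3))
    def test_degree_and_betweenness_against_enumeration(self, seed):
        g = net.giant_component(random_weighted_graph(seed + 80, n_max=8, p=0.6))
        d = net.network_descriptives(g)
        stats = d["node_stats"]
        # degree oracle
        for n in g.nodes:
            assert stats.loc[n, "degree"] == sum(1 for _ in g.neighbors(n))
        # betweenness oracle: enumerate weighted shortest paths directly
        nodes = sorted(g.nodes)
        counts = {n: 0.0 for n in nodes}
        for s, t in itertools.combinations(nodes, 2):
            paths = list(nx.all_shortest_paths(
                g, s, t, weight=lambda u, v, e: 1.0 - e["weight"]))
            for path in paths:
                for mid in path[1:-1]:
                    counts[mid] += 1.0 / len(paths)
        n = len(nodes)
        scale = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 1.0
        for node in nodes:
            assert stats.loc[node, "betweenness"] == pytest.approx(
                counts[node] * scale, abs=1e-9)
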