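"""Scoring checks: betweenness against a path-enumeration oracle, and the
importance score S = |B*| + |D*| against a fully hand-worked example."""

import itertools
from collections import deque

import numpy as np
import pytest

from micnet.network import LayerNetwork, MultilayerNetwork
from micnet.scoring import (
    betweenness,
    cross_layer_degree,
    importance_scores,
    jarque_bera,
    rank_nodes,
    standardize_diff,
)

SQRT3 = np.sqrt(3.0)


def oracle_betweenness(adj):
    """All shortest paths by BFS layering + recursive enumeration; fractional
    counting per pair, normalized by (n-1)(n-2)/2. Independent of networkx."""
    n = adj.shape[0]
    nbrs = [set(np.flatnonzero(adj[i])) for i in range(n)]

    def all_shortest_paths(s, t):
        dist = {s: 0}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in nbrs[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        if t not in dist:
            return []
        paths = []

        def back(node, path):
            if node == s:
                paths.append(list(reversed(path + [s])))
                return
            for u in nbrs[node]:
                if dist.get(u, -1) == dist[node] - 1:
                    back(u, path + [node])

        back(t, [])
        return paths

    scores = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for k in range(n):
            if k in (s, t):
                continue
            through = sum(1 for p in paths if k in p)
            scores[k] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2
    return scores / norm


def layer(adj, nodes=None, layer_name="miRNA", condition="normal", tau=0.35):
    adj = np.asarray(adj, dtype=int)
    nodes = nodes or [f"n{i}" for i in range(adj.shape[0])]
    return LayerNetwork(layer_name, condition, nodes, adj, tau)


class TestBetweenness:
    def test_path_graph_center_dominates(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        b = betweenness(layer(adj, ["a", "b", "c"]))
        assert b["b"] == pytest.approx(1.0)  # sole middle of the only pair
        assert b["a"] == b["c"] == 0.0

    def test_complete_graph_all_zero(self):
        adj = 1 - np.eye(5, dtype=int)
        assert set(betweenness(layer(adj)).values()) == {0.0}

    def test_isolated_nodes_score_zero(self):
        adj = np.zeros((4, 4), dtype=int)
        adj[0, 1] = adj[1, 0] = 1
        b = betweenness(layer(adj))
        assert all(v == 0.0 for v in b.values())

    @pytest.mark.parametrize("trial", range(12))
    def test_matches_path_enumeration_oracle(self, trial):
        rng = np.random.default_rng(500 + trial)
        n = int(rng.integers(5, 13))
        adj = (rng.uniform(size=(n, n)) < 0.3).astype(int)
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        got = betweenness(layer(adj))
        want = oracle_betweenness(adj)
        for i in range(n):
            assert got[f"n{i}"] == pytest.approx(want[i], abs=1e-12)


def multilayer(a_m, a_p, cross, condition):
    return MultilayerNetwork(
        layer(a_m, [f"m{i + 1}" for i in range(a_m.shape[0])], "miRNA", condition),
        layer(a_p, [f"p{i + 1}" for i in range(a_p.shape[0])], "protein", condition),
        np.asarray(cross, dtype=int),
    )


def hand_example():
    """4 miRNAs, 2 proteins; one intra edge and one cross edge vanish in cancer."""
    a_m_normal = np.zeros((4, 4), int)
    a_m_normal[0, 1] = a_m_normal[1, 0] = 1
    a_m_normal[1, 2] = a_m_normal[2, 1] = 1
    a_m_cancer = np.zeros((4, 4), int)
    a_m_cancer[0, 1] = a_m_cancer[1, 0] = 1
    a_p = np.zeros((2, 2), int)
    cross_normal = [[1, 0], [0, 1], [0, 0], [0, 0]]
    cross_cancer = [[1, 0], [0, 0], [0, 0], [0, 0]]
    return (
        multilayer(a_m_normal, a_p, cross_normal, "normal"),
        multilayer(a_m_cancer, a_p, cross_cancer, "tumor"),
    )


class TestCrossLayerDegree:
    def test_counts_only_interlayer_edges(self):
        normal, _ = hand_example()
        d = cross_layer_degree(normal)
        # m2 has an intra edge to m1/m3 but only one cross edge
        assert d == {"m1": 1, "m2": 1, "m3": 0, "m4": 0, "p1": 1, "p2": 1}

    @pytest.mark.parametrize("seed", range(5))
    def test_handshake_identity(self, seed):
        rng = np.random.default_rng(seed)
        cross = (rng.uniform(size=(6, 4)) < 0.4).astype(int)
        mln = multilayer(np.zeros((6, 6), int), np.zeros((4, 4), int), cross, "normal")
        d = cross_layer_degree(mln)
        mir_sum = sum(d[f"m{i + 1}"] for i in range(6))
        prot_sum = sum(d[f"p{i + 1}"] for i in range(4))
        assert mir_sum == prot_sum == int(cross.sum())


class TestStandardize:
    def test_three_point_example_population_sd(self):
        out = standardize_diff({"a": 1.0, "b": 2.0, "c": 3.0})
        root = np.sqrt(3 / 2)  # 1/sd with population sd sqrt(2/3)
        assert out["a"] == pytest.approx(-root)
        assert out["b"] == 0.0
        assert out["c"] == pytest.approx(root)

    def test_constant_input_warns_all_zero(self):
        with pytest.warns(UserWarning, match="zero variance"):
            out = standardize_diff({"a": 2.0, "b": 2.0})
        assert out == {"a": 0.0, "b": 0.0}

    def test_output_mean_zero_sd_one(self):
        rng = np.random.default_rng(8)
        vals = {f"n{i}": float(v) for i, v in enumerate(rng.normal(size=30))}
        out = np.array(list(standardize_diff(vals).values()))
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std() == pytest.approx(1.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            standardize_diff({})


class TestJarqueBera:
    def test_zero_statistic_for_skewless_mesokurtic_sample(self):
        # 1/6 of mass at +a, 1/6 at -a, 2/3 at 0: skew 0, kurtosis exactly 3
        v = np.array([1.0, 1.0, -1.0, -1.0] + [0.0] * 8)
        stat, p = jarque_bera(v)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_normal_samples_rarely_rejected(self):
        hits = sum(
            jarque_bera(np.random.default_rng(s).normal(size=500))[1] > 0.05
            for s in range(20)
        )
        assert hits >= 18

    def test_heavy_tails_rejected(self):
        hits = sum(
            jarque_bera(np.random.default_rng(s).standard_t(df=2, size=500))[1] < 0.05
            for s in range(20)
        )
        assert hits >= 18

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            jarque_bera([1.0, 2.0])
        with pytest.raises(ValueError, match="zero-variance"):
            jarque_bera(np.ones(20))


class TestImportanceScores:
    def test_identical_networks_score_zero(self):
        normal, _ = hand_example()
        twin = multilayer(
            normal.mirna_layer.adjacency,
            normal.protein_layer.adjacency,
            normal.cross_adjacency,
            "tumor",
        )
        table = importance_scores(normal, twin)
        assert (table["score"] == 0.0).all()
        assert (table["b_diff"] == 0.0).all()
        assert (table["d_diff"] == 0.0).all()

    def test_hand_worked_example_exact(self):
        """Every intermediate of the 4-miRNA/2-protein example, computed by
        hand: m2's betweenness drops by 1/3 and it loses its only cross
        edge, so B* = D* = sqrt(3) and S = 2*sqrt(3); the other miRNAs sit
        at -sqrt(3)/3 in both components."""
        normal, cancer = hand_example()
        t = importance_scores(normal, cancer).set_index("node")
        assert t.loc["m2", "b_normal"] == pytest.approx(1 / 3)
        assert t.loc["m2", "b_cancer"] == 0.0
        assert t.loc["m2", "d_normal"] == 1 and t.loc["m2", "d_cancer"] == 0
        assert t.loc["m2", "b_star"] == pytest.approx(SQRT3)
        assert t.loc["m2", "d_star"] == pytest.approx(SQRT3)
        assert t.loc["m2", "score"] == pytest.approx(2 * SQRT3)
        for m in ("m1", "m3", "m4"):
            assert t.loc[m, "b_star"] == pytest.approx(-SQRT3 / 3)
            assert t.loc[m, "d_star"] == pytest.approx(-SQRT3 / 3)
            assert t.loc[m, "score"] == pytest.approx(2 * SQRT3 / 3)
        # protein layer: betweenness flat -> only degree part differs
        assert t.loc["p1", "d_star"] == pytest.approx(-1.0)
        assert t.loc["p2", "d_star"] == pytest.approx(1.0)
        assert t.loc["p1", "score"] == t.loc["p2", "score"] == pytest.approx(1.0)
        assert int(t.loc["m2", "rank"]) == 1

    def test_symmetric_in_condition_arguments(self):
        normal, cancer = hand_example()
        fwd = importance_scores(normal, cancer).set_index("node")["score"]
        rev_n = multilayer(cancer.mirna_layer.adjacency, cancer.protein_layer.adjacency,
                           cancer.cross_adjacency, "normal")
        rev_c = multilayer(normal.mirna_layer.adjacency, normal.protein_layer.adjacency,
                           normal.cross_adjacency, "tumor")
        rev = importance_scores(rev_n, rev_c).set_index("node")["score"]
        for node in fwd.index:
            assert fwd[node] == pytest.approx(rev[node])

    def test_score_decomposition_exact(self):
        normal, cancer = hand_example()
        t = importance_scores(normal, cancer)
        resid = t["score"] - t["b_star"].abs() - t["d_star"].abs()
        assert (resid == 0.0).all()
        assert (t["betweenness_part"] + t["degree_part"] == t["score"]).all()

    def test_differential_cross_layer_hub_has_max_degree_diff(self):
        rng = np.random.default_rng(99)
        for seed in range(5):
            cross_n = (np.random.default_rng(seed).uniform(size=(6, 4)) < 0.15).astype(int)
            cross_n[2, :] = 1  # m3 is a normal-specific cross-layer hub
            cross_c = cross_n.copy()
            cross_c[2, :] = 0
            normal = multilayer(np.zeros((6, 6), int), np.zeros((4, 4), int), cross_n, "normal")
            cancer = multilayer(np.zeros((6, 6), int), np.zeros((4, 4), int), cross_c, "tumor")
            t = importance_scores(normal, cancer)
            mir = t[t["layer"] == "miRNA"].set_index("node")
            assert mir["d_diff"].idxmax() == "m3"
            assert int(mir.loc["m3", "rank"]) == 1


class TestRankNodes:
    def _table(self):
        normal, cancer = hand_example()
        return importance_scores(normal, cancer)

    def test_tie_broken_by_node_id(self):
        import pandas as pd

        t = pd.DataFrame(
            {
                "node": ["a", "b", "c"],
                "layer": "miRNA",
                "b_star": [2.0, 5.0, 5.0],
                "d_star": [0.0, 0.0, 0.0],
                "score": [2.0, 5.0, 5.0],
            }
        )
        out = rank_nodes(t, top_n=3)
        assert list(out["node"]) == ["b", "c", "a"]

    def test_top_n_larger_than_table_returns_all(self):
        out = rank_nodes(self._table(), top_n=100)
        assert len(out) == 6

    def test_invalid_top_n(self):
        with pytest.raises(ValueError, match="top_n"):
            rank_nodes(self._table(), 0)
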