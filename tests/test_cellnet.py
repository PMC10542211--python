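"""Pearson similarity, thresholded k-NN graphs, MCL, small-cluster merging."""

from __future__ import annotations

import igraph
import numpy as np
import pandas as pd
import pytest

from melliseq import cellnet


def graph_from_edges(edges: dict[tuple[str, str], float]) -> igraph.Graph:
    nodes = sorted({n for e in edges for n in e})
    g = igraph.Graph()
    g.add_vertices(nodes)
    g.add_edges(list(edges))
    g.es["weight"] = list(edges.values())
    return g


def edge_set(g: igraph.Graph) -> set[frozenset]:
    names = g.vs["name"]
    return {frozenset((names[e.source], names[e.target])) for e in g.es}


class TestPairwisePearson:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),  # sum dx dy / sqrt(...) = 4/5
        ],
    )
    def test_known_pairs(self, a, b, expected):
        sim = cellnet.pairwise_pearson(np.array([a, b], dtype=float))
        assert sim[0, 1] == pytest.approx(expected, abs=1e-12)
        assert sim[1, 0] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(np.diag(sim), 1.0)

    def test_zero_variance_profile_gets_zero_similarity(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            sim = cellnet.pairwise_pearson(np.array([[1.0, 1, 1], [1, 2, 3]]))
        assert sim[0, 1] == 0.0
        assert sim[0, 0] == 1.0

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError):
            cellnet.pairwise_pearson(np.array([[1.0], [2.0]]))


class TestBuildKnnGraph:
    def test_all_similarities_below_threshold_gives_edgeless_graph(self):
        sim = np.full((4, 4), 0.5)
        np.fill_diagonal(sim, 1.0)
        g = cellnet.build_knn_graph(sim, ["a", "b", "c", "d"])
        assert g.vcount() == 4 and g.ecount() == 0

    def test_small_clique_fully_connected(self):
        sim = np.full((3, 3), 0.9)
        np.fill_diagonal(sim, 1.0)
        g = cellnet.build_knn_graph(sim, ["a", "b", "c"], k=20)
        assert edge_set(g) == {frozenset("ab"), frozenset("bc"), frozenset("ac")}

    def test_union_symmetrization_hand_example(self):
        # k=1: a,b pick each other (0.9); c picks b (0.8 >= 0.77); d picks
        # nothing above threshold -> edges {a-b, b-c}
        names = ["a", "b", "c", "d"]
        sim = np.eye(4)
        sim[0, 1] = sim[1, 0] = 0.9
        sim[1, 2] = sim[2, 1] = 0.8
        sim[0, 2] = sim[2, 0] = 0.5
        sim[0, 3] = sim[3, 0] = 0.6
        sim[1, 3] = sim[3, 1] = 0.6
        sim[2, 3] = sim[3, 2] = 0.7
        g = cellnet.build_knn_graph(sim, names, k=1, r_min=0.77)
        assert edge_set(g) == {frozenset("ab"), frozenset("bc")}
        assert g.vcount() == 4

    def test_invariant_to_node_ordering(self):
        rng = np.random.default_rng(0)
        profiles = rng.normal(size=(12, 6))
        sim = cellnet.pairwise_pearson(profiles)
        names = [f"n{i}" for i in range(12)]
        g1 = cellnet.build_knn_graph(sim, names, k=3, r_min=0.2)
        perm = rng.permutation(12)
        g2 = cellnet.build_knn_graph(sim[np.ix_(perm, perm)], [names[i] for i in perm], k=3, r_min=0.2)
        assert edge_set(g1) == edge_set(g2)

    def test_k_zero_rejected(self):
        with pytest.raises(ValueError):
            cellnet.build_knn_graph(np.eye(2), ["a", "b"], k=0)


class TestPruneLowDegree:
    def test_isolated_node_removed(self):
        g = graph_from_edges({("a", "b"): 1, ("b", "c"): 1, ("a", "c"): 1})
        g.add_vertices(["lonely"])
        out = cellnet.prune_low_degree(g, min_degree=2)
        assert sorted(out.vs["name"]) == ["a", "b", "c"]

    def test_degree_three_in_k4_kept(self):
        edges = {(a, b): 1.0 for i, a in enumerate("abcd") for b in "abcd"[i + 1 :]}
        out = cellnet.prune_low_degree(graph_from_edges(edges), min_degree=3)
        assert out.vcount() == 4

    def test_single_pass_removes_whole_path(self):
        g = graph_from_edges({("a", "b"): 1, ("b", "c"): 1, ("c", "d"): 1})
        out = cellnet.prune_low_degree(g, min_degree=3)
        assert out.vcount() == 0


def clique(names: list[str], w: float = 1.0) -> dict:
    return {(a, b): w for i, a in enumerate(names) for b in names[i + 1 :]}


def dense_mcl_oracle(A: np.ndarray, inflation=1.6, expansion=2, iters=300) -> list[set[int]]:
    """Minimal dense-matrix MCL, written independently of the implementation:
    self-loops = max incident weight, column normalization, expansion/
    inflation loop without pruning, attractor rows read as clusters."""
    n = A.shape[0]
    M = A.astype(float).copy()
    for i in range(n):
        inc = M[i][M[i] > 0]
        M[i, i] = inc.max() if inc.size else 1.0
    M /= M.sum(axis=0, keepdims=True)
    for _ in range(iters):
        M = np.linalg.matrix_power(M, expansion)
        M = M**inflation
        M /= M.sum(axis=0, keepdims=True)
    clusters = []
    for i in range(n):
        if M[i, i] > 1e-6:
            members = set(np.flatnonzero(M[i] > 1e-6).tolist()) | {i}
            merged = False
            for c in clusters:
                if c & members:
                    c |= members
                    merged = True
                    break
            if not merged:
                clusters.append(members)
    return clusters


class TestMCL:
    def assignment_groups(self, assignment: pd.Series) -> set[frozenset]:
        return {
            frozenset(assignment.index[assignment == c]) for c in assignment.unique()
        }

    def test_single_clique_is_one_cluster(self):
        g = graph_from_edges(clique(list("abcd")))
        asg = cellnet.mcl_cluster(g)
        assert asg.nunique() == 1

    def test_two_bridged_cliques_split_and_match_oracle(self):
        names1, names2 = list("abcd"), list("efgh")
        edges = {**clique(names1, 0.95), **clique(names2, 0.95), ("d", "e"): 0.77}
        g = graph_from_edges(edges)
        asg = cellnet.mcl_cluster(g)
        assert self.assignment_groups(asg) == {frozenset(names1), frozenset(names2)}
        # independent dense oracle on the identical matrix
        order = g.vs["name"]
        A = np.zeros((8, 8))
        for e in g.es:
            A[e.source, e.target] = A[e.target, e.source] = e["weight"]
        oracle = dense_mcl_oracle(A)
        oracle_named = {frozenset(order[i] for i in c) for c in oracle}
        assert oracle_named == self.assignment_groups(asg)

    def test_disconnected_triangles_give_two_clusters(self):
        g = graph_from_edges({**clique(list("abc")), **clique(list("xyz"))})
        asg = cellnet.mcl_cluster(g)
        assert self.assignment_groups(asg) == {frozenset("abc"), frozenset("xyz")}

    @pytest.mark.parametrize("sizes", [(3, 4), (5, 3, 6), (4, 4, 3, 5)])
    def test_high_inflation_recovers_disconnected_cliques_exactly(self, sizes):
        edges = {}
        expected = set()
        for ci, size in enumerate(sizes):
            names = [f"c{ci}n{j}" for j in range(size)]
            edges.update(clique(names))
            expected.add(frozenset(names))
        asg = cellnet.mcl_cluster(graph_from_edges(edges), inflation=4.0)
        assert self.assignment_groups(asg) == expected

    def test_cluster_ids_contiguous_by_descending_size(self):
        g = graph_from_edges({**clique(list("abc")), **clique(list("vwxyz"))})
        asg = cellnet.mcl_cluster(g)
        sizes = asg.value_counts()
        assert list(sizes.index) == [1, 2]
        assert sizes[1] == 5 and sizes[2] == 3

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            cellnet.mcl_cluster(igraph.Graph())


class TestMergeSmallClusters:
    def star_case(self):
        # small cluster S={s1..s3} connected to A (total weight 5.2) and B (3.1)
        edges = {}
        edges.update(clique([f"a{i}" for i in range(12)], 0.9))
        edges.update(clique([f"b{i}" for i in range(12)], 0.9))
        edges.update(clique(["s0", "s1", "s2"], 0.9))
        edges[("s0", "a0")] = 2.6
        edges[("s1", "a1")] = 2.6
        edges[("s2", "b0")] = 3.1
        g = graph_from_edges(edges)
        asg = pd.Series(
            {**{f"a{i}": 1 for i in range(12)}, **{f"b{i}": 2 for i in range(12)},
             "s0": 3, "s1": 3, "s2": 3}
        )
        return g, asg

    def test_small_cluster_merges_into_highest_weight_neighbour(self):
        g, asg = self.star_case()
        merged = cellnet.merge_small_clusters(asg, g, min_size=10)
        assert merged["s0"] == merged["a0"]
        assert merged.nunique() == 2

    def test_cluster_of_exactly_min_size_not_merged(self):
        edges = {**clique([f"a{i}" for i in range(10)], 0.9), **clique([f"b{i}" for i in range(12)], 0.9)}
        edges[("a0", "b0")] = 0.8
        g = graph_from_edges(edges)
        asg = pd.Series({**{f"a{i}": 2 for i in range(10)}, **{f"b{i}": 1 for i in range(12)}})
        merged = cellnet.merge_small_clusters(asg, g, min_size=10)
        assert merged.nunique() == 2

    def test_isolated_small_cluster_left_unchanged(self):
        edges = {**clique([f"a{i}" for i in range(12)], 0.9), **clique(["s0", "s1"], 0.9)}
        g = graph_from_edges(edges)
        asg = pd.Series({**{f"a{i}": 1 for i in range(12)}, "s0": 2, "s1": 2})
        merged = cellnet.merge_small_clusters(asg, g, min_size=10)
        assert merged.nunique() == 2

    def test_never_increases_cluster_count_nor_leaves_connected_small_clusters(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = 40
            sim = cellnet.pairwise_pearson(rng.normal(size=(n, 8)))
            names = [f"n{i}" for i in range(n)]
            g = cellnet.build_knn_graph(sim, names, k=4, r_min=0.0)
            asg = cellnet.mcl_cluster(g, inflation=4.0)
            merged = cellnet.merge_small_clusters(asg, g, min_size=10)
            assert merged.nunique() <= asg.nunique()
            sizes = merged.value_counts()
            inter = cellnet._intercluster_weights(g, merged)
            for c in sizes.index[sizes < 10]:
                assert not any(c in key for key in inter), "small cluster retained despite external edges"
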