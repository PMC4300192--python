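"""Adjacency thresholding, pruning, and topological-overlap similarity."""

import math

import numpy as np
import pytest

from fastgcn.correlation import PackedTriangular
from fastgcn.network import (
    AdjacencyNetwork,
    build_adjacency,
    prune_isolated,
    topological_similarity,
)
from fastgcn.significance import EdgeStatistics
from helpers import shared_neighbors_brute


def stats_with_q(q):
    """EdgeStatistics carrying only what adjacency construction reads."""
    q = np.asarray(q, dtype=float)
    t = len(q)
    k = int((1 + math.isqrt(1 + 8 * t)) // 2)
    rho = PackedTriangular(k=k, values=np.zeros(t))
    return EdgeStatistics(
        k=k, rho=rho, z=np.zeros(t), p=q.copy(), q=q, rho_bar=0.0, s=1.0
    )


def net_from_edges(k, edges, gene_ids=None):
    adj = np.zeros((k, k), dtype=np.int8)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return AdjacencyNetwork(
        gene_ids=gene_ids or [f"g{i}" for i in range(k)],
        adjacency=adj,
        connectivity=adj.sum(axis=1, dtype=np.int64),
        tau=0.05,
    )


class TestBuildAdjacency:
    def test_three_gene_enumeration(self):
        # packed pairs (B,A), (C,A), (C,B) for genes A, B, C
        net = build_adjacency(
            stats_with_q([0.01, 0.20, 0.04]), tau=0.05, gene_ids=["A", "B", "C"]
        )
        assert net.adjacency[1, 0] == 1  # A-B
        assert net.adjacency[2, 0] == 0  # A-C
        assert net.adjacency[2, 1] == 1  # B-C
        np.testing.assert_array_equal(net.connectivity, [1, 2, 1])

    def test_tau_one_gives_complete_graph(self):
        net = build_adjacency(stats_with_q(np.random.default_rng(0).uniform(size=45)), tau=1.0)
        assert (net.connectivity == 9).all()

    def test_tau_zero_keeps_only_exact_zero_q(self):
        net = build_adjacency(stats_with_q([0.0, 1e-300, 0.5]), tau=0.0)
        assert net.n_edges == 1

    def test_symmetry_zero_diagonal_and_degree_sum(self):
        rng = np.random.default_rng(1)
        net = build_adjacency(stats_with_q(rng.uniform(size=190)), tau=0.3)
        assert np.array_equal(net.adjacency, net.adjacency.T)
        assert (np.diag(net.adjacency) == 0).all()
        assert net.connectivity.sum() == 2 * net.n_edges

    def test_monotone_in_tau(self):
        rng = np.random.default_rng(2)
        q = rng.uniform(size=4950)
        low = build_adjacency(stats_with_q(q), tau=0.1)
        high = build_adjacency(stats_with_q(q), tau=0.4)
        assert (high.adjacency >= low.adjacency).all()

    @pytest.mark.parametrize("tau", [-0.01, 1.01])
    def test_tau_out_of_range(self, tau):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            build_adjacency(stats_with_q([0.5]), tau=tau)


class TestPruneIsolated:
    def test_identity_when_nothing_isolated(self):
        net = net_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        pruned = prune_isolated(net)
        assert pruned.gene_ids == net.gene_ids
        np.testing.assert_array_equal(pruned.adjacency, net.adjacency)

    def test_single_edge_among_five_nodes(self):
        net = net_from_edges(5, [(0, 1)], gene_ids=list("ABCDE"))
        pruned = prune_isolated(net)
        assert pruned.gene_ids == ["A", "B"]
        np.testing.assert_array_equal(pruned.original_indices, [0, 1])
        assert (pruned.connectivity >= 1).all()

    def test_all_isolated_is_an_error(self):
        net = net_from_edges(4, [])
        with pytest.raises(ValueError, match="tau"):
            prune_isolated(net)


class TestTopologicalSimilarity:
    def test_triangle_all_ones(self):
        sim = topological_similarity(net_from_edges(3, [(0, 1), (1, 2), (0, 2)]))
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_array_equal(sim.s[off], np.ones(6))

    def test_three_node_path(self):
        sim = topological_similarity(net_from_edges(3, [(0, 1), (1, 2)]))
        assert sim.s[0, 2] == pytest.approx(1.0)  # identical neighborhoods {B}
        assert sim.s[0, 1] == pytest.approx(0.5)
        assert sim.s[1, 2] == pytest.approx(0.5)

    def test_single_edge_pair(self):
        sim = topological_similarity(net_from_edges(2, [(0, 1)]))
        assert sim.s[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            k = int(rng.integers(5, 61))
            density = rng.uniform(0.1, 0.5)
            adj = (rng.uniform(size=(k, k)) < density).astype(np.int8)
            adj = np.triu(adj, 1)
            adj = adj + adj.T
            keep = adj.sum(axis=1) > 0
            adj = adj[np.ix_(keep, keep)]
            if adj.shape[0] < 2:
                continue
            net = net_from_edges(adj.shape[0], zip(*np.nonzero(np.triu(adj))))
            sim = topological_similarity(net)
            h_brute = shared_neighbors_brute(adj)
            off = ~np.eye(adj.shape[0], dtype=bool)
            np.testing.assert_array_equal(sim.h[off], h_brute[off])
            assert ((sim.s >= 0) & (sim.s <= 1)).all()
            assert (np.diag(sim.s) == 1).all()
            np.testing.assert_array_equal(sim.s, sim.s.T)

    def test_identical_neighbor_sets_give_similarity_one(self):
        # two leaves attached to the same hub
        sim = topological_similarity(net_from_edges(3, [(0, 2), (1, 2)]))
        assert sim.s[0, 1] == pytest.approx(1.0)

    def test_unpruned_input_rejected(self):
        net = net_from_edges(3, [(0, 1)])
        with pytest.raises(ValueError, match="pruned"):
            topological_similarity(net)
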