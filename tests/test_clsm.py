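"""Edge-level analysis: nuisance regression, z-matrix, subgraph extraction."""

import itertools

import networkx as nx
import numpy as np
import pytest

from svrlsm.behavior import ResidualScores
from svrlsm.clsm import (Subgraph, ZMatrix, max_disconnected_subgraph,
                         node_disconnection_count, nuisance_residualize_edges,
                         run_clsm, significant_edges)
from svrlsm.disconnectome import devectorize_edges, edge_pairs
from svrlsm.engine import SvrConfig


class TestNuisanceRegression:
    def test_zero_variance_covariate_rejected(self):
        mat = np.random.default_rng(0).random((6, 4))
        with pytest.raises(ValueError, match="zero variance"):
            nuisance_residualize_edges(mat, {"flat": np.ones(6)})

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(1)
        mat = rng.random((8, 3))
        v = rng.random(8)
        with pytest.raises(ValueError, match="volume.*months|months.*volume"):
            nuisance_residualize_edges(mat, {"volume": v, "months": 2 * v + 1})

    def test_column_linear_in_covariate_residualizes_to_zero(self):
        rng = np.random.default_rng(2)
        vol = rng.random(10)
        mat = np.column_stack([3 * vol + 1, rng.random(10)])
        out = nuisance_residualize_edges(mat, {"volume": vol})
        assert np.allclose(out[:, 0], 0.0, atol=1e-10)

    def test_four_subject_hand_ols(self):
        # One covariate x = [0,1,2,3], column y = [1,2,2,4]:
        # slope 0.9, intercept 0.9, residuals [0.1, 0.2, -0.7, 0.4].
        x = np.array([0.0, 1.0, 2.0, 3.0])
        mat = np.array([[1.0], [2.0], [2.0], [4.0]])
        out = nuisance_residualize_edges(mat, {"x": x})
        assert np.allclose(out[:, 0], [0.1, 0.2, -0.7, 0.4], atol=1e-12)

    def test_residual_columns_orthogonal_to_covariates(self):
        rng = np.random.default_rng(3)
        mat = rng.random((15, 6))
        covs = {"a": rng.random(15), "b": rng.random(15)}
        out = nuisance_residualize_edges(mat, covs)
        for v in covs.values():
            assert np.allclose((v - v.mean()) @ out, 0.0, atol=1e-8)


class TestRunClsm:
    def test_single_included_edge_yields_one_defined_pair(self):
        rng = np.random.default_rng(4)
        n_nodes = 4
        mat = rng.random((20, 6))
        included = np.zeros(6, dtype=bool)
        included[2] = True  # edge (1, 4)
        target = ResidualScores(list(range(20)), rng.normal(size=20))
        zmat = run_clsm(mat, target, SvrConfig(n_permutations=100, seed=0),
                        included_edges=included)
        defined = ~np.isnan(zmat.z)
        assert defined.sum() == 2  # one undirected pair, two cells
        assert defined[0, 3] and defined[3, 0]

    def test_non_triangular_column_count_rejected(self):
        target = ResidualScores(list(range(8)), np.zeros(8))
        with pytest.raises(ValueError, match="triangular"):
            run_clsm(np.zeros((8, 5)), target,
                     SvrConfig(n_permutations=100, seed=0))


class TestSignificantEdges:
    def _zmat(self, zvec, n_nodes=3):
        z = devectorize_edges(np.asarray(zvec, dtype=float), n_nodes)
        np.fill_diagonal(z, np.nan)
        return ZMatrix(n_nodes=n_nodes, z=z,
                       included_edges=np.ones(len(zvec), dtype=bool))

    def test_all_zero_gives_empty_set(self):
        assert significant_edges(self._zmat([0.0, 0.0, 0.0])) == {}

    def test_strict_boundary(self):
        edges = significant_edges(self._zmat([-2.0, -1.65, -1.0]))
        assert set(edges) == {(1, 2)}
        assert edges[(1, 2)] == pytest.approx(2.0)

    def test_each_undirected_edge_reported_once(self):
        edges = significant_edges(self._zmat([-2.0, -3.0, -1.7]))
        assert set(edges) == {(1, 2), (1, 3), (2, 3)}
        assert all(i < j for (i, j) in edges)


def brute_force_max_connected_subgraph(edges: dict) -> float:
    """Oracle: enumerate every connected edge subset, return best weight."""
    best = 0.0
    edge_list = list(edges)
    for r in range(1, len(edge_list) + 1):
        for subset in itertools.combinations(edge_list, r):
            g = nx.Graph(subset)
            if nx.is_connected(g):
                best = max(best, sum(edges[e] for e in subset))
    return best


class TestMaxDisconnectedSubgraph:
    def test_single_edge(self):
        sub = max_disconnected_subgraph({(1, 2): 2.0})
        assert sub.nodes == {1, 2}
        assert sub.total_weight == pytest.approx(2.0)

    def test_five_node_toy_prefers_heavier_component(self):
        edges = {(1, 2): 2.0, (2, 3): 2.0, (4, 5): 3.0}
        sub = max_disconnected_subgraph(edges, solver="exact")
        assert sub.nodes == {1, 2, 3}
        assert sub.total_weight == pytest.approx(4.0)

    def test_empty_input_gives_empty_subgraph(self):
        sub = max_disconnected_subgraph({})
        assert sub.nodes == set() and sub.total_weight == 0.0

    def test_non_positive_weight_rejected(self):
        with pytest.raises(ValueError):
            max_disconnected_subgraph({(1, 2): 0.0})

    def test_exact_solver_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(2, 7))
            pairs = [(i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1)]
            keep = rng.random(len(pairs)) < 0.5
            edges = {p: float(rng.random() + 0.05)
                     for p, k in zip(pairs, keep) if k}
            if not edges:
                continue
            sub = max_disconnected_subgraph(edges, solver="exact")
            assert sub.total_weight == pytest.approx(
                brute_force_max_connected_subgraph(edges))

    def test_greedy_mostly_agrees_with_exact_on_random_graphs(self):
        # Edge density 0.3 mimics thresholded z-matrices, whose surviving
        # edges cluster into one dominant component; greedy only loses when
        # the single heaviest edge sits in a minor component.
        rng = np.random.default_rng(8)
        agree = 0
        for _ in range(50):
            n = 12
            pairs = [(i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1)]
            keep = rng.random(len(pairs)) < 0.3
            edges = {p: float(rng.random() + 0.05)
                     for p, k in zip(pairs, keep) if k}
            if not edges:
                agree += 1
                continue
            exact = max_disconnected_subgraph(edges, solver="exact")
            greedy = max_disconnected_subgraph(edges, solver="greedy")
            agree += exact.total_weight == pytest.approx(greedy.total_weight)
        assert agree >= 45

    def test_subgraph_is_connected_and_degree_consistent(self):
        rng = np.random.default_rng(9)
        pairs = [(i, j) for i in range(1, 9) for j in range(i + 1, 9)]
        edges = {p: float(rng.random() + 0.01) for p in pairs
                 if rng.random() < 0.3}
        if edges:
            sub = max_disconnected_subgraph(edges)
            g = nx.Graph(list(sub.edges))
            assert nx.is_connected(g)
            for node, deg in sub.node_degree_counts.items():
                assert deg == g.degree(node)


class TestNodeDisconnectionCount:
    def test_empty_set_gives_zeros(self):
        counts = node_disconnection_count({}, n_nodes=4)
        assert all(v == 0 for v in counts.values())

    def test_star_graph_counts(self):
        edges = {(1, 2): 1.0, (1, 3): 1.0, (1, 4): 1.0, (1, 5): 1.0}
        counts = node_disconnection_count(edges)
        assert counts[1] == 4
        assert all(counts[k] == 1 for k in (2, 3, 4, 5))

    def test_handshake_identity(self):
        rng = np.random.default_rng(10)
        edges = {(i, j): 1.0 for i in range(1, 7) for j in range(i + 1, 7)
                 if rng.random() < 0.5}
        counts = node_disconnection_count(edges, n_nodes=6)
        assert sum(counts.values()) == 2 * len(edges)
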