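import numpy as np
import pytest
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from modular_esn import (
    GraphSpec,
    WeightSpec,
    generate_graph,
    normalize_to,
    realized_mixing,
    spectral_radius,
    weight_matrix,
)
from modular_esn.graphs import ModularGraph, to_networkx, write_edge_list, write_membership


def spec500(mu, seed=0):
    return GraphSpec(n_nodes=500, n_communities=50, community_size=10, degree=6, mu=mu, seed=seed)


class TestGenerateGraph:
    @pytest.mark.parametrize("mu", [0.0, 0.1, 0.3, 0.5])
    def test_degree_regularity_and_edge_conservation(self, mu):
        """Every node has exactly `degree` incoming edges at every mu."""
        g = generate_graph(spec500(mu, seed=3))
        assert g.n_edges == 500 * 6
        in_degree = np.asarray(g.adjacency.sum(axis=1)).ravel()
        assert np.all(in_degree == 6)
        # no self-loops, no duplicate edges (a duplicate would sum to 2)
        assert g.adjacency.diagonal().sum() == 0
        assert g.adjacency.max() == 1

    @pytest.mark.parametrize("mu", [0.1, 0.3, 0.5])
    def test_realized_mixing_tracks_target(self, mu):
        g = generate_graph(spec500(mu, seed=5))
        assert abs(realized_mixing(g) - mu) < 0.02

    def test_mu_zero_gives_disconnected_communities(self):
        g = generate_graph(spec500(0.0, seed=1))
        assert realized_mixing(g) == 0.0
        n_comp, _ = connected_components(g.adjacency, directed=True, connection="weak")
        assert n_comp >= 50

    def test_mixing_monotone_in_target(self):
        """Mean realized mixing over seeds is non-decreasing in target mu."""
        mus = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5]
        means = [
            np.mean([realized_mixing(generate_graph(spec500(mu, seed=s))) for s in range(20)])
            for mu in mus
        ]
        assert all(a <= b for a, b in zip(means, means[1:]))

    def test_deterministic_per_seed(self):
        a = generate_graph(spec500(0.3, seed=9)).adjacency
        b = generate_graph(spec500(0.3, seed=9)).adjacency
        assert (a != b).nnz == 0

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError, match="internal stubs"):
            GraphSpec(n_nodes=500, n_communities=50, community_size=10, degree=12, mu=0.0)
        with pytest.raises(ValueError):
            GraphSpec(n_nodes=500, n_communities=49, community_size=10, degree=6, mu=0.2)
        with pytest.raises(ValueError):
            GraphSpec(n_nodes=500, n_communities=50, community_size=10, degree=6, mu=0.7)


class TestRealizedMixing:
    def _toy(self, rows, cols, membership):
        n = len(membership)
        adj = sparse.csr_array((np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n))
        spec = GraphSpec(n_nodes=n, n_communities=2, community_size=n // 2, degree=1, mu=0.5)
        return ModularGraph(adjacency=adj, membership=np.asarray(membership), spec=spec)

    def test_all_internal_edges(self):
        g = self._toy([0, 1, 3, 4], [1, 2, 4, 5], [0, 0, 0, 1, 1, 1])
        assert realized_mixing(g) == 0.0

    def test_half_cross_edges(self):
        g = self._toy([0, 3, 0, 3], [1, 4, 3, 0], [0, 0, 0, 1, 1, 1])
        assert realized_mixing(g) == 0.5

    def test_matches_brute_force_recount(self):
        g = generate_graph(spec500(0.3, seed=2))
        coo = g.adjacency.tocoo()
        cross = sum(
            1 for i, j in zip(coo.row, coo.col) if g.membership[i] != g.membership[j]
        )
        assert realized_mixing(g) == pytest.approx(cross / coo.nnz, abs=1e-15)

    def test_empty_graph_rejected(self):
        g = self._toy([0], [1], [0, 0, 0, 1, 1, 1])
        g.adjacency.data[:] = 0
        g.adjacency.eliminate_zeros()
        with pytest.raises(ValueError):
            realized_mixing(g)


class TestWeightMatrix:
    def test_constant_weights(self, small_graph):
        W = weight_matrix(small_graph, WeightSpec(w_low=1.0, w_high=1.0, w_scale=2.0, seed=0))
        assert np.all(W.data == 2.0)
        assert (W != 0).nnz == small_graph.n_edges

    def test_bounds_and_pattern(self):
        g = generate_graph(spec500(0.2, seed=4))
        W = weight_matrix(g, WeightSpec(seed=8))  # defaults [-0.2, 1] x 1.13
        assert W.data.min() >= -0.2 * 1.13
        assert W.data.max() <= 1.0 * 1.13
        assert ((W != 0) != (g.adjacency != 0)).nnz == 0

    def test_sample_mean_matches_uniform_expectation(self):
        g = generate_graph(spec500(0.2, seed=4))
        W = weight_matrix(g, WeightSpec(seed=8))
        expected = 1.13 * (1.0 - 0.2) / 2  # scale times uniform mean
        se = 1.13 * 1.2 / np.sqrt(12) / np.sqrt(W.nnz)
        assert abs(W.data.mean() - expected) < 4 * se

    def test_weight_stream_independent_of_topology(self, small_graph):
        W1 = weight_matrix(small_graph, WeightSpec(seed=1))
        W2 = weight_matrix(small_graph, WeightSpec(seed=2))
        W1b = weight_matrix(small_graph, WeightSpec(seed=1))
        assert not np.allclose(W1.data, W2.data)
        assert np.array_equal(W1.data, W1b.data)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            WeightSpec(w_low=1.0, w_high=0.0)
        with pytest.raises(ValueError):
            WeightSpec(w_scale=0.0)


class TestSpectralRadius:
    def test_zero_matrix(self):
        assert spectral_radius(np.zeros((4, 4))) == 0.0

    def test_swap_matrix(self):
        assert spectral_radius(np.array([[0.0, 1.0], [1.0, 0.0]])) == pytest.approx(1.0)

    def test_matches_dense_eigensolver(self):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(8, 8))
        oracle = np.max(np.abs(np.linalg.eigvals(M)))
        assert spectral_radius(M) == pytest.approx(oracle, abs=1e-8)
        assert spectral_radius(sparse.csr_array(M)) == pytest.approx(oracle, abs=1e-8)

    def test_normalize_to_sets_radius(self):
        rng = np.random.default_rng(1)
        M = sparse.csr_array(rng.normal(size=(10, 10)))
        assert spectral_radius(normalize_to(M, 0.95)) == pytest.approx(0.95, abs=1e-10)

    def test_normalize_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            normalize_to(np.zeros((3, 3)), 0.95)


class TestExports:
    def test_edge_list_roundtrip_counts(self, small_graph, tmp_path):
        W = weight_matrix(small_graph, WeightSpec(seed=0))
        path = tmp_path / "edges.tsv"
        write_edge_list(path, small_graph, W)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "source\ttarget\tweight"
        assert len(lines) - 1 == small_graph.n_edges

    def test_membership_table(self, small_graph, tmp_path):
        path = tmp_path / "membership.tsv"
        write_membership(path, small_graph)
        lines = path.read_text().strip().splitlines()
        assert len(lines) - 1 == small_graph.n_nodes

    def test_networkx_attributes(self, small_graph):
        g = to_networkx(small_graph)
        assert g.number_of_edges() == small_graph.n_edges
        assert g.nodes[0]["community"] == 0
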