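"""Density thresholding and graph-theoretic measures, validated against
closed forms and an independent brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fbandnet as fb
import bruteforce_oracle as oracle
from conftest import random_graph


def _weight_matrix(n, weights):
    """Symmetric matrix with given upper-triangle weights (row-major)."""
    mat = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mat[iu] = weights
    return mat + mat.T


class TestThresholding:
    def test_ten_percent_of_2850_is_285_edges(self, rng):
        mat = np.abs(rng.standard_normal((76, 76))) + 0.01
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 1.0)
        G = fb.threshold_by_density(mat, 0.10)
        assert G.n_edges == 285

    def test_full_density_gives_complete_graph(self, rng):
        mat = _weight_matrix(6, rng.uniform(0.1, 1.0, 15))
        G = fb.threshold_by_density(mat, 1.0)
        assert G.n_edges == 15

    def test_ties_at_cutoff_admitted_lexicographically(self):
        """Weights {0.9, 0.8, 0.8, 0.1, -0.5, -0.9} at density 0.5 keep the
        0.9 edge and both 0.8 ties."""
        mat = _weight_matrix(4, [0.9, 0.8, 0.8, 0.1, -0.5, -0.9])
        G = fb.threshold_by_density(mat, 0.5)
        kept = {(i, j) for i, j in zip(*np.triu_indices(4, 1)) if G.adjacency[i, j]}
        assert kept == {(0, 1), (0, 2), (0, 3)}

    def test_negative_weights_never_selected(self, caplog):
        mat = _weight_matrix(4, [0.5, 0.3, -0.9, -0.8, -0.7, -0.6])
        with caplog.at_level("WARNING"):
            G = fb.threshold_by_density(mat, 1.0)
        assert G.n_edges == 2
        assert "positive weights" in caplog.text

    def test_nested_across_density_grid(self, rng):
        mat = _weight_matrix(15, rng.uniform(-1, 1, 105))
        stack = fb.build_density_stack(mat, fb.density_grid(0.10, 0.50, 0.05))
        for lo, hi in zip(stack.graphs, stack.graphs[1:]):
            assert not (lo.adjacency & ~hi.adjacency).any()

    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError):
            fb.threshold_by_density(np.eye(4), 0.0)


class TestClosedFormMetrics:
    def test_triangle_and_star_clustering(self):
        tri = fb.make_toy_graph("complete", 3)
        assert np.allclose(fb.nodal_clustering(tri), 1.0)
        star = fb.make_toy_graph("star", 5)
        assert fb.nodal_clustering(star)[0] == 0.0

    def test_k4_minus_edge_clustering_and_local_efficiency(self):
        adj = np.ones((4, 4), dtype=bool)
        np.fill_diagonal(adj, False)
        adj[2, 3] = adj[3, 2] = False
        G = fb.Graph(adjacency=adj)
        # nodes 0 and 1 have degree 3 with 2 of 3 neighbor pairs connected
        assert fb.nodal_clustering(G)[0] == pytest.approx(2 / 3)
        # neighbors of 0 are {1,2,3}: d(1,2)=d(1,3)=1 and d(2,3)=2 within the
        # neighbor subgraph, so E_0 = (1 + 1 + 1/2)/3
        assert fb.local_efficiency(G)[0] == pytest.approx(5 / 6)

    def test_path_lengths_and_efficiency(self):
        k5 = fb.make_toy_graph("complete", 5)
        assert fb.characteristic_path_length(k5) == pytest.approx(1.0)
        assert fb.global_efficiency(k5) == pytest.approx(1.0)
        p3 = fb.make_toy_graph("path", 3)
        assert fb.characteristic_path_length(p3) == pytest.approx(1.2)
        assert fb.global_efficiency(p3) == pytest.approx(5 / 6)

    def test_disconnected_pairs_contribute_zero(self):
        adj = np.zeros((4, 4), dtype=bool)
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = True
        G = fb.Graph(adjacency=adj)
        assert fb.characteristic_path_length(G) == pytest.approx(3.0)

    def test_empty_graph_is_flagged_disconnected(self):
        G = fb.Graph(adjacency=np.zeros((4, 4), dtype=bool))
        assert np.isinf(fb.characteristic_path_length(G))
        assert fb.global_efficiency(G) == 0.0

    def test_betweenness_path_star_cycle(self):
        p3 = fb.make_toy_graph("path", 3)
        assert fb.betweenness(p3)[1] == pytest.approx(1.0)
        star = fb.make_toy_graph("star", 5)
        assert fb.betweenness(star)[0] == pytest.approx(1.0)
        c4 = fb.Graph.from_networkx(
            __import__("networkx").cycle_graph(4), n=4
        )
        assert np.allclose(fb.betweenness(c4), 1 / 6)

    def test_degree_and_strength(self, rng):
        mat = _weight_matrix(4, rng.uniform(0.1, 1.0, 6))
        G = fb.threshold_by_density(mat, 1.0)
        k, s = fb.degree_and_strength(G)
        assert np.array_equal(k, [3, 3, 3, 3])
        assert np.allclose(s, mat.sum(axis=1))
        iso = fb.Graph(adjacency=np.zeros((3, 3), dtype=bool))
        k0, s0 = fb.degree_and_strength(iso)
        assert k0[0] == 0 and s0[0] == 0

    def test_ring_lattice_clustering_closed_form(self):
        """Ring lattice C = 3(k-2)/(4(k-1)); k=4 gives 0.5."""
        G = fb.make_toy_graph("ring_lattice", 76, k=4)
        assert np.allclose(fb.nodal_clustering(G), 0.5)


class TestModulesAndRoles:
    def test_two_cliques_recovered(self):
        import networkx as nx
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        G = fb.Graph.from_networkx(g, n=10)
        part = fb.detect_modules(G)
        assert len(np.unique(part)) == 2
        assert len(np.unique(part[:5])) == 1 and len(np.unique(part[5:])) == 1

    def test_complete_graph_single_module(self):
        part = fb.detect_modules(fb.make_toy_graph("complete", 6))
        assert len(np.unique(part)) == 1

    def test_empty_graph_singleton_modules(self):
        part = fb.detect_modules(fb.Graph(adjacency=np.zeros((5, 5), dtype=bool)))
        assert len(np.unique(part)) == 5

    def test_planted_two_block_partition_recovered(self):
        import networkx as nx
        g = nx.stochastic_block_model([20, 20], [[0.9, 0.05], [0.05, 0.9]], seed=7)
        G = fb.Graph.from_networkx(g, n=40)
        part = fb.detect_modules(G)
        truth = np.repeat([0, 1], 20)
        # plain Rand index over all node pairs
        same_t = truth[:, None] == truth[None, :]
        same_p = part[:, None] == part[None, :]
        iu = np.triu_indices(40, 1)
        rand = (same_t[iu] == same_p[iu]).mean()
        assert rand >= 0.95

    def test_participation_formula_cases(self):
        adj = np.zeros((7, 7), dtype=bool)
        # node 0 with 4 edges split 2/2 across modules {1,2} and {3,4}
        for j in (1, 2, 3, 4):
            adj[0, j] = adj[j, 0] = True
        G = fb.Graph(adjacency=adj)
        part = np.array([0, 0, 0, 1, 1, 2, 2])
        y = fb.participation_coefficient(G, part)
        assert y[0] == pytest.approx(0.5)
        # all edges of node 1 inside its own module
        assert y[1] == pytest.approx(0.0)
        # 3-way 1/1/1 split gives 2/3
        adj2 = np.zeros((4, 4), dtype=bool)
        adj2[0, 1:] = adj2[1:, 0] = True
        y2 = fb.participation_coefficient(
            fb.Graph(adjacency=adj2), np.array([0, 0, 1, 2])
        )
        assert y2[0] == pytest.approx(2 / 3)

    def test_within_module_z_star_and_clique(self):
        star = fb.make_toy_graph("star", 4)
        z = fb.within_module_degree_z(star, np.zeros(4, dtype=int))
        # within-degrees (3,1,1,1): mean 1.5, population SD sqrt(3)/2
        assert z[0] == pytest.approx(1.5 / (np.sqrt(3) / 2))
        clique = fb.make_toy_graph("complete", 5)
        assert np.allclose(
            fb.within_module_degree_z(clique, np.zeros(5, dtype=int)), 0.0
        )

    def test_singleton_module_returns_zero_with_warning(self, caplog):
        G = fb.make_toy_graph("path", 3)
        with caplog.at_level("WARNING"):
            z = fb.within_module_degree_z(G, np.array([0, 0, 1]))
        assert z[2] == 0.0
        assert "singleton" in caplog.text


class TestRandomReference:
    def test_degree_sequence_preserved(self, rng):
        from fbandnet.topology import _rewired
        G = random_graph(rng, 12, 0.4)
        R = _rewired(G, rng)
        assert np.array_equal(np.sort(R.degrees()), np.sort(G.degrees()))

    def test_complete_graph_references_itself(self):
        G = fb.make_toy_graph("complete", 6)
        c_rand, l_rand = fb.random_reference(G, n_rand=3, seed=0)
        assert c_rand == pytest.approx(1.0)
        assert l_rand == pytest.approx(1.0)
        assert fb.smallworldness(G, n_rand=3, seed=0) == pytest.approx(1.0)

    def test_ring_lattice_more_clustered_than_random(self):
        G = fb.make_toy_graph("ring_lattice", 76, k=8)
        m = fb.small_world_metrics(G, n_rand=100, seed=0)
        assert m.c_norm > 1

    def test_erdos_renyi_sigma_near_one(self):
        G = fb.make_toy_graph("erdos_renyi", 76, seed=0, p=304 / 2850)
        sigma = fb.smallworldness(G, n_rand=100, seed=0)
        assert sigma == pytest.approx(1.0, abs=0.2)

    def test_deterministic_given_seed(self, rng):
        G = random_graph(rng, 20, 0.3)
        a = fb.random_reference(G, n_rand=5, seed=42)
        b = fb.random_reference(G, n_rand=5, seed=42)
        assert a == b


class TestMetricCurves:
    def test_auc_is_mean_on_uniform_grid(self, rng):
        mat = _weight_matrix(12, rng.uniform(0.01, 1.0, 66))
        stack = fb.build_density_stack(mat, fb.density_grid(0.1, 0.5, 0.1))
        curves = fb.metric_curves(stack, metrics=("degree",), global_metrics=True)
        c = curves["degree"]
        assert np.allclose(c.auc, np.asarray(c.values).mean(axis=0))
        assert curves["c_net"].auc == pytest.approx(
            np.mean(curves["c_net"].values)
        )

    def test_linear_curve_auc_is_midpoint(self):
        curve = fb.MetricCurve("m", np.linspace(0.1, 0.5, 5), np.linspace(2, 6, 5))
        assert curve.auc == pytest.approx(4.0)

    def test_single_density_auc_is_value(self):
        curve = fb.MetricCurve("m", np.array([0.2]), np.array([3.3]))
        assert curve.auc == pytest.approx(3.3)

    def test_nonuniform_grid_rejected(self, rng):
        mat = _weight_matrix(8, rng.uniform(0.01, 1.0, 28))
        stack = fb.build_density_stack(mat, np.array([0.1, 0.2, 0.4]))
        with pytest.raises(ValueError, match="uniform"):
            fb.metric_curves(stack)


class TestBruteForceEquivalence:
    def test_metrics_match_oracle_on_random_graphs(self, rng):
        """Matrix/BFS implementations agree with path enumeration to 1e-10."""
        for _ in range(40):
            G = random_graph(rng, int(rng.integers(4, 13)))
            adj = G.adjacency.astype(int)
            assert np.allclose(
                fb.nodal_clustering(G), oracle.clustering_coefficients(adj),
                atol=1e-10,
            )
            assert np.allclose(
                fb.local_efficiency(G), oracle.local_efficiency(adj), atol=1e-10
            )
            L = fb.characteristic_path_length(G)
            L_ref = oracle.harmonic_path_length(adj)
            assert (np.isinf(L) and np.isinf(L_ref)) or L == pytest.approx(L_ref, abs=1e-10)
            assert fb.global_efficiency(G) == pytest.approx(
                oracle.global_efficiency(adj), abs=1e-10
            )
            assert np.allclose(
                fb.betweenness(G), oracle.betweenness_normalized(adj), atol=1e-10
            )
            part = fb.detect_modules(G)
            assert np.allclose(
                fb.participation_coefficient(G, part),
                oracle.participation(adj, part),
                atol=1e-10,
            )
            assert np.allclose(
                fb.within_module_degree_z(G, part),
                oracle.within_module_z(adj, part),
                atol=1e-10,
            )

    def test_ranges_hold_on_random_graphs(self, rng):
        for _ in range(20):
            G = random_graph(rng, 10)
            part = fb.detect_modules(G)
            for vec in (
                fb.nodal_clustering(G),
                fb.local_efficiency(G),
                fb.participation_coefficient(G, part),
                fb.betweenness(G),
            ):
                assert (vec >= -1e-12).all() and (vec <= 1 + 1e-12).all()
            L = fb.characteristic_path_length(G)
            assert L >= 1.0


@settings(max_examples=30, derandomize=True, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_density_stack_edge_counts_and_nesting(seed):
    """For any weight matrix, thresholded graphs hit the rounded edge
    target (when enough positive weights exist) and are nested."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 20))
    mat = _weight_matrix(n, rng.uniform(-1, 1, n * (n - 1) // 2))
    densities = fb.density_grid(0.1, 0.5, 0.1)
    stack = fb.build_density_stack(mat, densities)
    n_pos = int((mat[np.triu_indices(n, 1)] > 0).sum())
    for d, G in zip(densities, stack.graphs):
        target = int(np.floor(d * n * (n - 1) / 2 + 0.5))
        assert G.n_edges == min(target, n_pos)
    for lo, hi in zip(stack.graphs, stack.graphs[1:]):
        assert not (lo.adjacency & ~hi.adjacency).any()
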