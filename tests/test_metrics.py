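import numpy as np
import pytest

from covnet import (
    SparsityGrid,
    auc_over_grid,
    betweenness_centrality,
    characteristic_path_length,
    clustering_coefficients,
    compute_metric_curves,
    degree_centrality,
    global_efficiency,
    local_efficiency,
    nodal_efficiency,
    rewire_degree_preserving,
    small_world_indices,
)
from covnet.exceptions import ParameterError, UndefinedAUCError, ValidationError
from covnet.network import CovarianceMatrix, GraphStack, build_graph_stack
from conftest import complete_graph, ring_lattice
from oracles import (
    betweenness_oracle,
    clustering_oracle,
    eglob_oracle,
    local_eff_oracle,
    lp_oracle,
    nodal_eff_oracle,
    random_graph,
)


class TestSmallGraphExamples:
    def test_degree_triangle_and_path(self, path_graph):
        np.testing.assert_array_equal(degree_centrality(complete_graph(3)), [2, 2, 2])
        np.testing.assert_array_equal(degree_centrality(path_graph), [1, 2, 1])

    def test_betweenness_path_middle_node(self, path_graph):
        np.testing.assert_allclose(betweenness_centrality(path_graph), [0.0, 1.0, 0.0])

    def test_betweenness_star_center(self):
        star = np.zeros((4, 4), dtype=np.uint8)
        star[0, 1:] = star[1:, 0] = 1
        np.testing.assert_allclose(betweenness_centrality(star), [3.0, 0, 0, 0])

    def test_clustering_complete_and_star(self):
        _, cp = clustering_coefficients(complete_graph(4))
        assert cp == pytest.approx(1.0)
        star = np.zeros((4, 4), dtype=np.uint8)
        star[0, 1:] = star[1:, 0] = 1
        nodal, cp = clustering_coefficients(star)
        assert cp == 0.0 and np.all(nodal == 0)

    def test_clustering_triangle_with_pendant(self):
        adj = np.zeros((4, 4), dtype=np.uint8)
        for i, j in [(0, 1), (1, 2), (0, 2), (0, 3)]:
            adj[i, j] = adj[j, i] = 1
        nodal, _ = clustering_coefficients(adj)
        assert nodal[0] == pytest.approx(1 / 3)

    def test_path_length_examples(self, path_graph):
        assert characteristic_path_length(path_graph) == pytest.approx(4 / 3)
        assert characteristic_path_length(complete_graph(4)) == pytest.approx(1.0)

    def test_path_length_finite_pairs_convention(self):
        two_k2 = np.zeros((4, 4), dtype=np.uint8)
        two_k2[0, 1] = two_k2[1, 0] = two_k2[2, 3] = two_k2[3, 2] = 1
        assert characteristic_path_length(two_k2) == pytest.approx(1.0)

    def test_path_length_empty_graph_nan(self):
        with pytest.warns(UserWarning, match="no edges"):
            assert np.isnan(characteristic_path_length(np.zeros((3, 3), dtype=np.uint8)))

    def test_efficiency_examples(self, path_graph):
        assert global_efficiency(complete_graph(5)) == pytest.approx(1.0)
        assert global_efficiency(path_graph) == pytest.approx((1 + 1 + 0.5) / 3)

    def test_asymmetric_input_rejected(self):
        bad = np.array([[0, 1], [0, 0]])
        for fn in (degree_centrality, betweenness_centrality, global_efficiency):
            with pytest.raises(ValidationError):
                fn(bad)


class TestOracleEquivalence:
    """Implementation kernels vs naive brute-force algorithms on random graphs."""

    @pytest.fixture(scope="class")
    def graphs(self):
        rng = np.random.default_rng(42)
        out = []
        for _ in range(60):
            n = int(rng.integers(4, 13))
            out.append(random_graph(rng, n, float(rng.uniform(0.15, 0.8))))
        return out

    def test_all_metrics_match_bruteforce(self, graphs):
        for adj in graphs:
            np.testing.assert_array_equal(degree_centrality(adj), adj.sum(axis=1))
            nodal_c, cp = clustering_coefficients(adj)
            np.testing.assert_allclose(nodal_c, clustering_oracle(adj), atol=1e-9)
            lp = characteristic_path_length(adj) if adj.sum() else np.nan
            if adj.sum():
                assert lp == pytest.approx(lp_oracle(adj), abs=1e-9)
                assert global_efficiency(adj) == pytest.approx(eglob_oracle(adj), abs=1e-10)
                np.testing.assert_allclose(nodal_efficiency(adj), nodal_eff_oracle(adj),
                                           atol=1e-10)
                np.testing.assert_allclose(local_efficiency(adj), local_eff_oracle(adj),
                                           atol=1e-10)
                np.testing.assert_allclose(betweenness_centrality(adj),
                                           betweenness_oracle(adj), atol=1e-9)

    def test_betweenness_matches_networkx(self, graphs):
        nx = pytest.importorskip("networkx")
        for adj in graphs[:20]:
            g = nx.from_numpy_array(adj)
            expected = nx.betweenness_centrality(g, normalized=False)
            np.testing.assert_allclose(
                betweenness_centrality(adj),
                [expected[i] for i in range(adj.shape[0])], atol=1e-9,
            )


class TestRewiring:
    def test_complete_graph_unchanged(self):
        k5 = complete_graph(5)
        np.testing.assert_array_equal(rewire_degree_preserving(k5, seed=3), k5)

    def test_degree_sequence_preserved(self):
        rng = np.random.default_rng(7)
        for trial in range(100):
            adj = random_graph(rng, int(rng.integers(5, 20)), 0.3)
            out = rewire_degree_preserving(adj, seed=trial)
            np.testing.assert_array_equal(out.sum(axis=1), adj.sum(axis=1))
            assert np.array_equal(out, out.T)
            assert np.all(np.diag(out) == 0)

    def test_cycle_rewires_to_new_edge_set(self):
        cycle = ring_lattice(8, 2)
        changed = sum(
            not np.array_equal(rewire_degree_preserving(cycle, seed=s), cycle)
            for s in range(200)
        )
        assert changed > 180  # > 90% of seeded trials


class TestSmallWorldIndices:
    def test_complete_graph_exactly_one(self):
        sw = small_world_indices(complete_graph(10), n_null=20, seed=0)
        assert sw["gamma"] == 1.0 and sw["lambda"] == 1.0 and sw["sigma"] == 1.0

    def test_sigma_is_gamma_over_lambda(self):
        adj = random_graph(np.random.default_rng(5), 30, 0.2)
        sw = small_world_indices(adj, n_null=50, seed=1)
        assert sw["sigma"] == pytest.approx(sw["gamma"] / sw["lambda"], rel=1e-12)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        adj = random_graph(rng, 20, 0.25)
        perm = rng.permutation(20)
        sw1 = small_world_indices(adj, n_null=200, seed=2)
        sw2 = small_world_indices(adj[np.ix_(perm, perm)], n_null=200, seed=2)
        # stochastic null: indices agree within Monte Carlo error
        assert sw1["gamma"] == pytest.approx(sw2["gamma"], rel=0.15)
        assert sw1["lambda"] == pytest.approx(sw2["lambda"], rel=0.05)

    def test_gamma_matches_independent_null_implementation(self):
        nx = pytest.importorskip("networkx")
        adj = ring_lattice(40, 4)
        rng = np.random.default_rng(3)
        cps = []
        for _ in range(100):
            g = nx.from_numpy_array(adj)
            nx.double_edge_swap(g, nswap=10 * g.number_of_edges(), max_tries=10**6,
                                seed=int(rng.integers(2**31)))
            cps.append(nx.average_clustering(g))
        gamma_nx = (clustering_coefficients(adj)[1]) / np.mean(cps)
        sw = small_world_indices(adj, n_null=100, seed=4)
        assert sw["gamma"] == pytest.approx(gamma_nx, rel=0.2)

    def test_low_null_count_rejected(self):
        with pytest.raises(ParameterError):
            small_world_indices(complete_graph(5), n_null=5)


class TestAUC:
    def test_constant_curve(self):
        grid = SparsityGrid()
        c = 3.7
        assert auc_over_grid(np.full(36, c), grid) == pytest.approx(0.35 * c, abs=1e-12)

    def test_linear_curve_closed_form(self):
        grid = SparsityGrid()
        assert auc_over_grid(grid.as_array(), grid) == pytest.approx(0.07875, abs=1e-12)

    def test_matches_fine_grid_refinement(self):
        grid = SparsityGrid()
        rng = np.random.default_rng(12)
        curve = rng.random(36)
        s = grid.as_array()
        fine = np.linspace(s[0], s[-1], 36 * 64 - 63)
        refined = np.trapezoid(np.interp(fine, s, curve), fine)
        assert auc_over_grid(curve, grid) == pytest.approx(refined, abs=1e-12)

    def test_all_nan_curve_raises(self):
        with pytest.raises(UndefinedAUCError):
            auc_over_grid(np.full(36, np.nan), SparsityGrid())

    def test_leading_nan_suffix_rule(self):
        grid = SparsityGrid(0.1, 0.4, 0.1)
        curve = np.array([np.nan, 1.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="suffix"):
            assert auc_over_grid(curve, grid) == pytest.approx(0.2)


class TestMetricCurves:
    @pytest.fixture(scope="class")
    def complete_stack(self):
        from covnet.atlases import AtlasSpec

        atlas = AtlasSpec(name="toy6", roi_names=tuple(f"r{i}" for i in range(6)))
        grid = SparsityGrid(0.99, 0.99, 0.01)
        adj = complete_graph(6)
        return GraphStack(grid=grid, adjacency=[adj], edge_counts=[15], atlas=atlas)

    def test_complete_graph_sigma_identically_one(self, complete_stack):
        curves = compute_metric_curves(complete_stack, n_null=20, seed=0)
        assert (curves.global_curves["sigma"] == 1.0).all()
        assert (curves.global_curves["Cp"] == 1.0).all()

    def test_deterministic_given_seed(self, small_cohorts):
        from covnet import covariance_matrix, residualize

        cohort, _ = small_cohorts
        stack = build_graph_stack(covariance_matrix(residualize(cohort), "A"),
                                  SparsityGrid(0.1, 0.2, 0.05))
        c1 = compute_metric_curves(stack, n_null=30, seed=5)
        c2 = compute_metric_curves(stack, n_null=30, seed=5)
        assert c1.global_curves.equals(c2.global_curves)
        for p in c1.nodal_curves:
            assert c1.nodal_curves[p].equals(c2.nodal_curves[p])
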