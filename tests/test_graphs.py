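"""Graph measures against independent oracles (networkx, brute force)."""

import itertools

import networkx as nx
import numpy as np
import pytest

from comagraph import (
    DensityGrid,
    clustering_coefficient,
    global_efficiency,
    metric_auc,
    modularity,
    modularity_q,
    proportional_threshold,
)
from comagraph.connectivity import ConnectivityMatrix

from conftest import (
    floyd_warshall_efficiency,
    random_connectivity,
    random_weight_matrix,
    set_partitions,
    triangle_clustering_bruteforce,
)


class TestDensityGrid:
    def test_default_grid_has_nine_thresholds(self):
        grid = DensityGrid()
        assert len(grid) == 9
        np.testing.assert_allclose(grid.densities, np.arange(0.05, 0.46, 0.05))

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            DensityGrid((0.3, 0.2))
        with pytest.raises(ValueError):
            DensityGrid((0.0, 0.5))


class TestProportionalThreshold:
    def test_full_density_is_identity(self, rng):
        w = random_weight_matrix(rng, 8, p_edge=1.0)
        np.testing.assert_array_equal(proportional_threshold(w, 1.0), w)

    def test_three_largest_of_six_kept(self, rng):
        w = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        weights = np.array([0.1, 0.6, 0.3, 0.9, 0.2, 0.5])
        w[iu] = weights
        w = w + w.T
        out = proportional_threshold(w, 0.5)
        kept = np.sort(out[iu][out[iu] > 0])
        np.testing.assert_allclose(kept, [0.5, 0.6, 0.9])  # sort oracle

    @pytest.mark.parametrize("n", [5, 10, 23, 50])
    def test_edge_count_matches_definition(self, rng, n):
        w = random_weight_matrix(rng, n, p_edge=1.0)
        for d in DensityGrid().densities:
            out = proportional_threshold(w, d)
            k_expected = int(np.floor(d * n * (n - 1) / 2 + 0.5))
            assert np.count_nonzero(out[np.triu_indices(n, 1)]) == k_expected

    def test_zero_edge_request_rejected(self):
        with pytest.raises(ValueError):
            proportional_threshold(np.eye(3) * 0, 0.01)

    def test_sparse_input_warns_and_keeps_all(self, rng):
        w = np.zeros((6, 6))
        w[0, 1] = w[1, 0] = 0.5
        with pytest.warns(UserWarning, match="retaining all nonzero"):
            out = proportional_threshold(w, 0.9)
        assert np.count_nonzero(out) == 2


class TestClusteringCoefficient:
    def test_unit_triangle(self):
        w = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float)
        assert clustering_coefficient(w) == pytest.approx(1.0)

    def test_star_has_no_triangles(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        assert clustering_coefficient(w) == pytest.approx(0.0)

    def test_against_triangle_enumeration(self, rng):
        for _ in range(30):
            w = random_weight_matrix(rng, int(rng.integers(4, 9)))
            if w.max() == 0:
                continue
            assert clustering_coefficient(w) == pytest.approx(
                triangle_clustering_bruteforce(w), abs=1e-10
            )

    def test_against_networkx_onnela(self, rng):
        """Independent oracle: networkx weighted clustering (Onnela)."""
        for _ in range(10):
            w = random_weight_matrix(rng, 7)
            if w.max() == 0:
                continue
            g = nx.from_numpy_array(w / w.max())
            expect = np.mean(list(nx.clustering(g, weight="weight").values()))
            assert clustering_coefficient(w) == pytest.approx(expect, abs=1e-10)


class TestGlobalEfficiency:
    def test_complete_unit_graph(self):
        w = 1.0 - np.eye(4)
        assert global_efficiency(w) == pytest.approx(1.0)

    def test_three_node_path(self):
        w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
        assert global_efficiency(w) == pytest.approx(5 / 6)

    def test_against_floyd_warshall(self, rng):
        for _ in range(30):
            w = random_weight_matrix(rng, 8)
            if w.max() == 0:
                continue
            assert global_efficiency(w) == pytest.approx(
                floyd_warshall_efficiency(w), abs=1e-10
            )

    def test_disconnected_pairs_contribute_zero(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        # only the (0,1) ordered pairs contribute: 2/12
        assert global_efficiency(w) == pytest.approx(2 / 12)

    def test_nondecreasing_in_density(self, rng):
        conn = random_connectivity(rng, 20)
        vals = [
            global_efficiency(proportional_threshold(conn, d))
            for d in DensityGrid().densities
        ]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


class TestModularity:
    def test_single_community_q_is_zero(self, rng):
        w = random_weight_matrix(rng, 6, p_edge=1.0)
        assert modularity_q(w, np.zeros(6, int)) == pytest.approx(0.0)

    def test_two_disconnected_triangles(self):
        w = np.zeros((6, 6))
        for i, j in itertools.combinations(range(3), 2):
            w[i, j] = w[j, i] = 1.0
        for i, j in itertools.combinations(range(3, 6), 2):
            w[i, j] = w[j, i] = 1.0
        q, labels = modularity(w, n_restarts=10, seed=0)
        assert q == pytest.approx(0.5)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1

    def test_seeded_reproducibility(self, rng):
        w = random_weight_matrix(rng, 12)
        q1, l1 = modularity(w, n_restarts=5, seed=11)
        q2, l2 = modularity(w, n_restarts=5, seed=11)
        assert q1 == q2
        np.testing.assert_array_equal(l1, l2)

    def test_matches_exhaustive_partition_search(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 8))
            w = random_weight_matrix(rng, n)
            if w.sum() == 0:
                continue
            q, _ = modularity(w, n_restarts=20, seed=int(rng.integers(2**31)))
            best = max(modularity_q(w, lab) for lab in set_partitions(n))
            assert q == pytest.approx(best, abs=1e-9)
            assert q <= 1.0

    def test_zero_edge_graph_rejected(self):
        with pytest.raises(ValueError):
            modularity(np.zeros((4, 4)))


class TestMetricAUC:
    def test_constant_metric_returns_constant(self, rng):
        conn = random_connectivity(rng, 12)
        assert metric_auc(conn, lambda w: 0.7, DensityGrid()) == pytest.approx(0.7)

    def test_exactly_nine_evaluations_on_default_grid(self, rng):
        conn = random_connectivity(rng, 12)
        calls = []
        metric_auc(conn, lambda w: calls.append(1) or 1.0, DensityGrid())
        assert len(calls) == 9

    def test_linear_curve_closed_form(self, rng):
        """A metric linear in density integrates to the midpoint value."""
        conn = random_connectivity(rng, 12)
        counter = iter(np.linspace(2.0, 5.0, 9))
        assert metric_auc(conn, lambda w: next(counter), DensityGrid()) == pytest.approx(
            (2.0 + 5.0) / 2
        )

    def test_node_relabeling_invariance(self, rng):
        conn = random_connectivity(rng, 10)
        perm = rng.permutation(10)
        permuted = ConnectivityMatrix(conn.weights[np.ix_(perm, perm)])
        a = metric_auc(conn, clustering_coefficient, DensityGrid())
        b = metric_auc(permuted, clustering_coefficient, DensityGrid())
        assert a == pytest.approx(b, abs=1e-10)

    def test_metric_error_annotated_with_density(self, rng):
        conn = random_connectivity(rng, 10)

        def bad(w):
            raise ValueError("boom")

        with pytest.raises(ValueError, match="density 0.05"):
            metric_auc(conn, bad, DensityGrid())
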