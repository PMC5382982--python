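import numpy as np
import pytest

from rsnet.graphs import BinaryGraph, ConnectivityMatrix, SparsityGrid
from rsnet.metrics import (
    auc_over_sparsity,
    clustering_coefficient,
    greedy_modularity,
    local_efficiency,
    node_degree,
    path_metrics,
    random_reference,
    shortest_path_matrix,
    small_world_profile,
    subject_profile,
)
from rsnet.synthetic import make_lattice_graph, make_random_graph

from oracles import (
    best_partition_oracle,
    clustering_oracle,
    degree_oracle,
    efficiency_oracle,
    floyd_warshall_oracle,
    modularity_oracle,
    random_adjacency,
)


def _graph(adj):
    return BinaryGraph(np.asarray(adj, dtype=np.int8), 0.5)


def _complete(n):
    a = np.ones((n, n), dtype=np.int8) - np.eye(n, dtype=np.int8)
    return _graph(a)


def _path3():
    a = np.zeros((3, 3), dtype=np.int8)
    a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = 1
    return _graph(a)


class TestClosedForms:
    def test_star_degrees(self):
        a = np.zeros((4, 4), dtype=np.int8)
        a[0, 1:] = a[1:, 0] = 1
        assert node_degree(_graph(a)).tolist() == [3, 1, 1, 1]

    def test_k5_degrees(self):
        assert node_degree(_complete(5)).tolist() == [4] * 5

    def test_triangle_clustering(self):
        np.testing.assert_allclose(clustering_coefficient(_complete(3)), 1.0)

    def test_path_clustering_zero(self):
        np.testing.assert_allclose(clustering_coefficient(_path3()), 0.0)

    def test_k4_minus_edge_clustering(self):
        a = np.ones((4, 4), dtype=np.int8) - np.eye(4, dtype=np.int8)
        a[2, 3] = a[3, 2] = 0
        c = clustering_coefficient(_graph(a))
        np.testing.assert_allclose(c, [2 / 3, 2 / 3, 1.0, 1.0])

    def test_complete_graph_distances(self):
        d = shortest_path_matrix(_complete(6))
        off = d[~np.eye(6, dtype=bool)]
        assert (off == 1).all() and (np.diag(d) == 0).all()

    def test_path_distance_two_hops(self):
        d = shortest_path_matrix(_path3())
        assert d[0, 2] == 2

    def test_complete_graph_path_metrics(self):
        pm = path_metrics(_complete(7))
        assert pm.char_path_length == pytest.approx(1.0)
        assert pm.global_efficiency == pytest.approx(1.0)
        np.testing.assert_allclose(pm.nodal_efficiency, 1.0)

    def test_path3_metrics(self):
        pm = path_metrics(_path3())
        assert pm.char_path_length == pytest.approx(4 / 3)
        assert pm.global_efficiency == pytest.approx(5 / 6)
        np.testing.assert_allclose(pm.nodal_efficiency, [3 / 4, 1.0, 3 / 4])

    def test_two_disjoint_edges_use_reachable_pairs(self):
        a = np.zeros((4, 4), dtype=np.int8)
        a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = 1
        pm = path_metrics(_graph(a))
        assert pm.char_path_length == pytest.approx(1.0)
        assert pm.global_efficiency == pytest.approx(1 / 3)

    def test_edgeless_graph_errors(self):
        with pytest.raises(ValueError):
            path_metrics(_graph(np.zeros((4, 4), dtype=np.int8)))


class TestOracleEquivalence:
    def test_metrics_match_bruteforce_on_random_graphs(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 31))
            adj = random_adjacency(rng, n)
            g = _graph(adj)
            assert node_degree(g).tolist() == degree_oracle(adj)
            np.testing.assert_allclose(clustering_coefficient(g), clustering_oracle(adj), atol=1e-12)
            np.testing.assert_array_equal(shortest_path_matrix(g), floyd_warshall_oracle(adj))
            if g.edge_count:
                cpl, eg, e = efficiency_oracle(adj)
                pm = path_metrics(g)
                assert pm.char_path_length == pytest.approx(cpl)
                assert pm.global_efficiency == pytest.approx(eg)
                np.testing.assert_allclose(pm.nodal_efficiency, e, atol=1e-12)

    def test_degree_sum_is_twice_edges(self, rng):
        for seed in range(30):
            g = make_random_graph(40, int(rng.integers(10, 200)), seed=seed)
            assert node_degree(g).sum() == 2 * g.edge_count


class TestRandomReference:
    def test_triangle_has_no_legal_swap(self):
        g = _complete(3)
        ref = random_reference(g, seed=0)
        np.testing.assert_array_equal(ref.adjacency, g.adjacency)

    def test_degree_multiset_preserved(self, rng):
        for seed in range(25):
            g = make_random_graph(30, 90, seed=seed)
            ref = random_reference(g, seed=seed + 1)
            np.testing.assert_array_equal(
                np.sort(node_degree(ref)), np.sort(node_degree(g))
            )
            assert (np.diag(ref.adjacency) == 0).all()

    def test_same_seed_reproduces_graph(self):
        g = make_random_graph(40, 150, seed=3)
        a = random_reference(g, seed=11)
        b = random_reference(g, seed=11)
        np.testing.assert_array_equal(a.adjacency, b.adjacency)

    def test_rewiring_actually_moves_edges(self):
        g = make_lattice_graph(50, 6)
        ref = random_reference(g, seed=5)
        assert not np.array_equal(ref.adjacency, g.adjacency)


class TestSmallWorld:
    def test_complete_graph_is_its_own_reference(self):
        prof = small_world_profile(_complete(10), n_rand=3, seed=0)
        assert prof.c_norm == pytest.approx(1.0)
        assert prof.l_norm == pytest.approx(1.0)
        assert prof.small_world == pytest.approx(1.0)

    def test_lattice_is_small_world_like(self):
        prof = small_world_profile(make_lattice_graph(100, 10), n_rand=10, seed=1)
        assert prof.small_world > 2.0

    def test_er_graph_near_unity(self):
        prof = small_world_profile(make_random_graph(100, 500, seed=2), n_rand=10, seed=3)
        assert 0.8 <= prof.small_world <= 1.2


class TestGreedyModularity:
    def test_two_cliques_half_modularity(self):
        a = np.zeros((20, 20), dtype=np.int8)
        a[:10, :10] = 1
        a[10:, 10:] = 1
        np.fill_diagonal(a, 0)
        res = greedy_modularity(_graph(a))
        assert res.n_modules == 2
        assert res.q == pytest.approx(0.5)

    def test_complete_graph_zero_modularity(self):
        res = greedy_modularity(_complete(8))
        assert res.q == pytest.approx(0.0, abs=1e-12)

    def test_reported_q_matches_oracle_formula(self, rng):
        for _ in range(20):
            adj = random_adjacency(rng, int(rng.integers(6, 25)))
            if adj.sum() == 0:
                continue
            res = greedy_modularity(_graph(adj))
            assert res.q == pytest.approx(modularity_oracle(adj, res.partition))

    def test_greedy_bounded_by_exhaustive_and_recovers_planted(self, rng):
        for _ in range(8):
            adj = random_adjacency(rng, 7)
            if adj.sum() == 0:
                continue
            res = greedy_modularity(_graph(adj))
            best_q, _ = best_partition_oracle(adj)
            assert res.q <= best_q + 1e-12
        # planted two-clique structure is recovered exactly
        a = np.zeros((8, 8), dtype=np.int8)
        a[:4, :4] = 1
        a[4:, 4:] = 1
        np.fill_diagonal(a, 0)
        a[0, 4] = a[4, 0] = 1  # single bridge
        res = greedy_modularity(_graph(a))
        assert sorted(tuple(sorted(c)) for c in res.partition) == [(0, 1, 2, 3), (4, 5, 6, 7)]

    def test_edgeless_graph_errors(self):
        with pytest.raises(ValueError):
            greedy_modularity(_graph(np.zeros((4, 4), dtype=np.int8)))


class TestAuc:
    def test_constant_curve(self):
        grid = SparsityGrid.default()
        assert auc_over_sparsity(np.full(10, 3.0), grid) == pytest.approx(0.45 * 3.0)

    def test_identity_curve_exact(self):
        grid = SparsityGrid.default()
        assert auc_over_sparsity(grid.as_array(), grid) == pytest.approx(0.12375)

    def test_zeros(self):
        assert auc_over_sparsity(np.zeros(10), SparsityGrid.default()) == 0.0

    def test_single_point_errors(self):
        with pytest.raises(ValueError):
            auc_over_sparsity(np.array([1.0]), np.array([0.05]))


class TestLocalEfficiency:
    def test_complete_graph_unit_local_efficiency(self):
        np.testing.assert_allclose(local_efficiency(_complete(5)), 1.0)

    def test_path_has_zero_local_efficiency(self):
        np.testing.assert_allclose(local_efficiency(_path3()), 0.0)


class TestSubjectProfile:
    @pytest.fixture(scope="class")
    def profile_input(self):
        rng = np.random.default_rng(42)
        z = rng.standard_normal((120, 30))
        # plant modular structure so Q decays with sparsity
        for m in range(3):
            z[:, m * 10 : (m + 1) * 10] += 1.2 * rng.standard_normal(120)[:, None]
        r = np.corrcoef(z, rowvar=False)
        np.fill_diagonal(r, 1.0)
        return ConnectivityMatrix(np.clip(r, -1, 1), subject_id="p1", group="sham")

    def test_modularity_decreases_with_sparsity(self, profile_input):
        prof = subject_profile(profile_input, n_rand=3, seed=0)
        q = prof.global_metrics["modularity"]
        assert q.iloc[0] > q.iloc[-1]

    def test_profile_is_seed_deterministic(self, profile_input):
        a = subject_profile(profile_input, n_rand=3, seed=9)
        b = subject_profile(profile_input, n_rand=3, seed=9)
        assert a.global_metrics.equals(b.global_metrics)
        assert a.nodal_auc.equals(b.nodal_auc)

    def test_identical_matrices_identical_profiles(self, profile_input):
        import dataclasses

        other = dataclasses.replace(profile_input, subject_id="p2")
        a = subject_profile(profile_input, n_rand=3, seed=4)
        b = subject_profile(other, n_rand=3, seed=4)
        assert a.global_metrics.equals(b.global_metrics)

    def test_global_efficiency_is_mean_nodal(self, profile_input):
        prof = subject_profile(profile_input, n_rand=2, seed=1)
        for sp, sub in prof.nodal.groupby("sparsity"):
            assert prof.global_metrics.loc[sp, "global_efficiency"] == pytest.approx(
                sub["efficiency"].mean()
            )

    def test_auc_bounds_for_bounded_measures(self, profile_input):
        prof = subject_profile(profile_input, n_rand=2, seed=2)
        assert ((prof.nodal_auc["clustering"] >= 0) & (prof.nodal_auc["clustering"] <= 0.45)).all()
        assert ((prof.nodal_auc["efficiency"] >= 0) & (prof.nodal_auc["efficiency"] <= 0.45)).all()
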