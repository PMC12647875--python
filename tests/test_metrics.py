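import numpy as np
import pytest

from lifespan_topology.metrics import (
    betweenness,
    clustering_and_local_efficiency,
    core_periphery,
    degree_strength,
    k_core_size,
    modularity,
    rewire_preserving_degree,
    s_core_size,
    select_gamma,
    shortest_path_metrics,
    small_worldness,
    subgraph_centrality,
)
from lifespan_topology.synthetic import generate_toy_network

from . import oracles
from .conftest import random_graph


class TestDegreeStrength:
    def test_complete_k4(self):
        ds = degree_strength(generate_toy_network("complete", 4))
        assert np.all(ds["degree"] == 3) and np.all(ds["strength"] == 3)

    def test_star_center_and_leaves(self):
        ds = degree_strength(generate_toy_network("star", 5))
        assert ds["strength"][0] == 4 and np.all(ds["strength"][1:] == 1)

    def test_weighted_strength_sums_weights(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 0.5
        m[0, 2] = m[2, 0] = 0.25
        assert degree_strength(m)["strength"][0] == 0.75


class TestShortestPaths:
    def test_unit_triangle(self):
        sp = shortest_path_metrics(generate_toy_network("ring", 3))
        assert sp["char_path_length"] == 1.0
        assert sp["global_efficiency"] == 1.0

    def test_path_p3_enumerated_pairs(self):
        sp = shortest_path_metrics(generate_toy_network("path", 3))
        assert sp["char_path_length"] == pytest.approx(4 / 3)
        assert sp["global_efficiency"] == pytest.approx(5 / 6)

    def test_inverse_weight_length(self):
        m = np.array([[0, 0.5], [0.5, 0]])
        sp = shortest_path_metrics(m)
        assert sp["char_path_length"] == 2.0
        assert sp["global_efficiency"] == 0.5

    def test_disconnected_flagged_and_efficiency_zero(self):
        sp = shortest_path_metrics(np.zeros((4, 4)))
        assert sp["global_efficiency"] == 0.0
        assert sp["disconnected"]


class TestClustering:
    def test_unit_triangle_is_one(self):
        cl = clustering_and_local_efficiency(generate_toy_network("ring", 3))
        np.testing.assert_allclose(cl["clustering"], 1.0)

    def test_star_is_zero(self):
        cl = clustering_and_local_efficiency(generate_toy_network("star", 5))
        np.testing.assert_allclose(cl["clustering"], 0.0)

    def test_geometric_mean_triangle(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 1.0
        m[1, 2] = m[2, 1] = 1.0
        m[0, 2] = m[2, 0] = 0.125
        cl = clustering_and_local_efficiency(m)
        np.testing.assert_allclose(cl["clustering"], 0.5)


class TestPathOracles:
    """Path-based metrics vs independent Floyd-Warshall / path-count
    oracles on all fixtures and random n <= 12 graphs."""

    def test_fixture_graphs(self, toy_graphs):
        for name, m in toy_graphs.items():
            sp = shortest_path_metrics(m)
            assert sp["global_efficiency"] == pytest.approx(
                oracles.global_efficiency_oracle(m), abs=1e-8
            ), name
            if not sp["disconnected"]:
                assert sp["char_path_length"] == pytest.approx(
                    oracles.char_path_length_oracle(m), abs=1e-8
                ), name
            np.testing.assert_allclose(
                betweenness(m), oracles.betweenness_oracle(m), atol=1e-8
            )
            np.testing.assert_allclose(
                clustering_and_local_efficiency(m)["clustering"],
                oracles.clustering_oracle(m),
                atol=1e-8,
            )

    def test_random_graphs(self, random_graphs):
        for m in random_graphs:
            assert shortest_path_metrics(m)["global_efficiency"] == pytest.approx(
                oracles.global_efficiency_oracle(m), abs=1e-8
            )
            assert shortest_path_metrics(m)["char_path_length"] == pytest.approx(
                oracles.char_path_length_oracle(m), abs=1e-8, nan_ok=True
            )
            np.testing.assert_allclose(
                betweenness(m), oracles.betweenness_oracle(m), atol=1e-8
            )
            np.testing.assert_allclose(
                clustering_and_local_efficiency(m)["clustering"],
                oracles.clustering_oracle(m),
                atol=1e-8,
            )


class TestSubgraphCentrality:
    def test_isolated_node_is_one(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 1.0
        assert subgraph_centrality(m)[2] == pytest.approx(1.0)

    def test_k2_is_cosh_one(self):
        m = generate_toy_network("complete", 2)
        np.testing.assert_allclose(subgraph_centrality(m), np.cosh(1.0))

    def test_triangle_closed_form(self):
        m = generate_toy_network("ring", 3)
        expected = np.exp(2) / 3 + 2 * np.exp(-1) / 3
        np.testing.assert_allclose(subgraph_centrality(m), expected)

    def test_matches_truncated_walk_series(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            m = random_graph(rng, 8, p=0.5)
            np.testing.assert_allclose(
                subgraph_centrality(m),
                oracles.subgraph_centrality_series_oracle(m),
                atol=1e-8,
            )


class TestModularity:
    def test_two_cliques_q_half(self, toy_graphs):
        q, labels = modularity(toy_graphs["two_cliques"], gamma=1.0, seed=0)
        assert q == pytest.approx(0.5)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]
        # exhaustive bipartition oracle agrees
        assert q == pytest.approx(
            oracles.best_bipartition_modularity(toy_graphs["two_cliques"]),
            abs=1e-10,
        )

    def test_single_community_q_zero(self):
        m = generate_toy_network("complete", 6)
        q = oracles.modularity_oracle(m, np.zeros(6, dtype=int), 1.0)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(0)
        n, b = 30, 3
        labels_true = np.repeat(np.arange(b), n // b)
        m = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        same = labels_true[iu[0]] == labels_true[iu[1]]
        p = np.where(same, 0.9, 0.05)
        w = (rng.random(iu[0].size) < p).astype(float)
        m[iu] = w
        m += m.T
        _, labels = modularity(m, gamma=1.0, seed=0)
        from sklearn.metrics import adjusted_rand_score

        assert len(set(labels)) >= 3
        assert adjusted_rand_score(labels_true, labels) > 0.9

    def test_local_optimality_of_partition(self):
        rng = np.random.default_rng(1)
        m = random_graph(rng, 12, p=0.4)
        gamma = 1.0
        q, labels = modularity(m, gamma=gamma, seed=0)
        for v in range(12):
            for new in set(labels) - {labels[v]}:
                moved = labels.copy()
                moved[v] = new
                assert (
                    oracles.modularity_oracle(m, moved, gamma) <= q + 1e-9
                )


class TestGammaSelection:
    def test_identical_distributions_give_zero_ks(self):
        # nulls of a complete graph are the graph itself, so observed
        # and null modularity samples coincide
        mats = [generate_toy_network("complete", 8) for _ in range(4)]
        sel = select_gamma(mats, gamma_grid=[0.6, 1.0], seed=0)
        np.testing.assert_allclose(sel.ks_statistics, 0.0, atol=1e-12)
        assert sel.selected_gamma == 0.6  # tie broken to smallest gamma

    def test_singleton_grid_returned(self):
        mats = [generate_toy_network("two_cliques", 10) for _ in range(3)]
        sel = select_gamma(mats, gamma_grid=[1.0], seed=0)
        assert sel.selected_gamma == 1.0

    def test_argmax_matches_stored_samples(self):
        rng = np.random.default_rng(7)
        mats = []
        for _ in range(4):
            base = generate_toy_network("two_cliques", 10)
            noise = random_graph(rng, 10, p=0.1)
            mats.append(np.clip(base + noise, 0, None))
        sel = select_gamma(mats, gamma_grid=[0.5, 1.0, 1.5], n_null=2, seed=0)
        from scipy.stats import ks_2samp

        recomputed = {
            g: ks_2samp(sel.observed_q[g], sel.null_q[g]).statistic
            for g in sel.observed_q
        }
        best = min(
            (g for g in recomputed),
            key=lambda g: (-recomputed[g], g),
        )
        assert sel.selected_gamma == best


class TestCorePeriphery:
    def test_ideal_block_matrix_attains_exhaustive_max(self):
        n, c = 8, 3
        m = np.zeros((n, n))
        m[:c, :] = 1.0
        m[:, :c] = 1.0
        np.fill_diagonal(m, 0)
        q, core = core_periphery(m, seed=0)
        q_best, _ = oracles.best_core_periphery(m)
        assert q == pytest.approx(q_best, abs=1e-10)
        assert set(np.flatnonzero(core)) == {0, 1, 2}

    def test_complete_graph_all_core_optimal(self):
        m = generate_toy_network("complete", 6)
        q, core = core_periphery(m, seed=0)
        q_best, _ = oracles.best_core_periphery(m)
        assert q == pytest.approx(q_best, abs=1e-10) == pytest.approx(1.0)

    def test_star_center_in_core(self):
        q, core = core_periphery(generate_toy_network("star", 5), seed=0)
        q_best, core_best = oracles.best_core_periphery(
            generate_toy_network("star", 5)
        )
        assert core[0]
        assert q == pytest.approx(q_best, abs=1e-10)


class TestCores:
    def test_k5_max_kcore(self):
        level, size = k_core_size(generate_toy_network("complete", 5))
        assert (level, size) == (4.0, 5)

    def test_path_p4_kcore(self):
        level, size = k_core_size(generate_toy_network("path", 4))
        assert (level, size) == (1.0, 4)

    def test_star_score_all_nodes_at_level_one(self):
        level, size = s_core_size(generate_toy_network("star", 5))
        assert level == pytest.approx(1.0)
        assert size == 5

    def test_peeling_invariant_to_node_relabeling(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            m = random_graph(rng, 10, p=0.5)
            perm = rng.permutation(10)
            mp = m[np.ix_(perm, perm)]
            assert k_core_size(m) == k_core_size(mp)
            lvl_a, sz_a = s_core_size(m)
            lvl_b, sz_b = s_core_size(mp)
            assert sz_a == sz_b and lvl_a == pytest.approx(lvl_b)

    def test_empty_graph_core_size_zero(self):
        assert k_core_size(np.zeros((4, 4)))[1] == 0
        assert s_core_size(np.zeros((4, 4)))[1] == 0


class TestSmallWorldness:
    def test_complete_graph_sigma_one(self):
        m = generate_toy_network("complete", 8)
        assert small_worldness(m, n_null=10, seed=0) == pytest.approx(1.0)

    def test_watts_strogatz_ring_exceeds_one(self):
        import networkx as nx

        g = nx.watts_strogatz_graph(50, 6, 0.1, seed=1)
        m = nx.to_numpy_array(g)
        assert small_worldness(m, n_null=10, seed=0) > 1.0

    def test_dense_random_graph_near_one(self):
        rng = np.random.default_rng(9)
        m = (rng.random((30, 30)) < 0.6).astype(float)
        m = np.triu(m, 1)
        m += m.T
        sigma = small_worldness(m, n_null=20, seed=0)
        assert 0.8 <= sigma <= 1.2

    def test_rewiring_preserves_degree_and_weights(self):
        rng = np.random.default_rng(10)
        m = random_graph(rng, 15, p=0.4)
        null = rewire_preserving_degree(m, np.random.default_rng(0))
        assert np.array_equal(
            np.count_nonzero(m, axis=1), np.count_nonzero(null, axis=1)
        )
        iu = np.triu_indices(15, 1)
        np.testing.assert_allclose(
            np.sort(m[iu][m[iu] > 0]), np.sort(null[iu][null[iu] > 0])
        )


class TestPermutationInvariance:
    def test_scalar_metrics_invariant_to_relabeling(self):
        rng = np.random.default_rng(12)
        m = random_graph(rng, 10, p=0.5)
        perm = rng.permutation(10)
        mp = m[np.ix_(perm, perm)]
        assert shortest_path_metrics(m)["global_efficiency"] == pytest.approx(
            shortest_path_metrics(mp)["global_efficiency"]
        )
        assert np.mean(
            clustering_and_local_efficiency(m)["clustering"]
        ) == pytest.approx(
            np.mean(clustering_and_local_efficiency(mp)["clustering"])
        )
        np.testing.assert_allclose(
            np.sort(betweenness(m)), np.sort(betweenness(mp)), atol=1e-8
        )
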