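"""Graph statistics against hand computations and brute-force oracles."""

import numpy as np
import pytest

from connview.core import ComputationError, Ordering, bind_matrix
from connview.stats import (
    ModulePartition,
    betweenness_centrality,
    clustering_coefficient,
    compute_all,
    detect_modules,
    eigenvector_centrality,
    global_efficiency,
    local_efficiency,
    modularity_Q,
    strength,
)

from conftest import names, network_from, random_network


def complete_graph(n):
    return network_from(1.0 - np.eye(n))


def path_graph(n):
    w = np.zeros((n, n))
    for i in range(n - 1):
        w[i, i + 1] = w[i + 1, i] = 1.0
    return network_from(w)


def star_graph(leaves):
    w = np.zeros((leaves + 1, leaves + 1))
    w[0, 1:] = w[1:, 0] = 1.0
    return network_from(w)


def twin_cliques(size=5):
    n = 2 * size
    w = np.zeros((n, n))
    for base in (0, size):
        block = slice(base, base + size)
        w[block, block] = 1.0
    np.fill_diagonal(w, 0.0)
    return network_from(w)


from oracles import brute_clustering, brute_efficiency, brute_modularity, lengths_of


# --- hand-computed examples ------------------------------------------------


class TestStrength:
    def test_zero_matrix(self):
        assert np.all(strength(network_from(np.zeros((4, 4)))).values == 0)

    def test_triangle_all_two(self):
        assert np.allclose(strength(complete_graph(3)).values, 2)

    def test_row_sum(self):
        w = np.zeros((3, 3))
        w[0, 1] = 3.0
        w[0, 2] = 2.0
        net = network_from(w + w.T)
        assert strength(net).values[0] == 5.0


class TestClustering:
    def test_complete_graph_all_one(self):
        for variant in ("binary", "weighted"):
            assert np.allclose(
                clustering_coefficient(complete_graph(4), variant).values, 1.0
            )

    def test_star_all_zero(self):
        assert np.all(clustering_coefficient(star_graph(4)).values == 0)

    def test_kite_matches_triangle_count_oracle(self):
        # 5-node kite: 4-clique plus a tail
        w = np.zeros((5, 5))
        w[:4, :4] = 1.0
        np.fill_diagonal(w, 0.0)
        w[3, 4] = w[4, 3] = 1.0
        net = network_from(w)
        assert np.allclose(
            clustering_coefficient(net, "binary").values, brute_clustering(w)
        )


class TestEfficiency:
    def test_complete_graph_is_one(self):
        assert global_efficiency(complete_graph(5), "binary") == pytest.approx(1.0)
        assert local_efficiency(complete_graph(5), "binary").values == pytest.approx(1.0)

    def test_edgeless_graph_is_zero(self):
        assert global_efficiency(network_from(np.zeros((4, 4)))) == 0.0

    def test_binary_path_three_nodes_is_five_sixths(self):
        assert global_efficiency(path_graph(3), "binary") == pytest.approx(5 / 6)

    def test_star_local_efficiency_zero(self):
        assert np.all(local_efficiency(star_graph(5)).values == 0)

    def test_random_graph_matches_brute_force(self):
        rng = np.random.default_rng(11)
        net = random_network(rng, 8, p=0.5)
        assert global_efficiency(net, "weighted") == pytest.approx(
            brute_efficiency(lengths_of(net.weights, "weighted"))
        )


class TestBetweenness:
    def test_path_center_one_endpoints_zero(self):
        assert np.allclose(betweenness_centrality(path_graph(3)).values, [0, 1, 0])

    def test_star_center_is_pair_count(self):
        values = betweenness_centrality(star_graph(4)).values
        assert values[0] == pytest.approx(6.0)  # C(4,2) pairs all via the hub
        assert np.all(values[1:] == 0)

    def test_complete_graph_all_zero(self):
        assert np.all(betweenness_centrality(complete_graph(5)).values == 0)


class TestEigenvector:
    def test_cycle_is_uniform(self):
        n = 6
        w = np.zeros((n, n))
        for i in range(n):
            w[i, (i + 1) % n] = w[(i + 1) % n, i] = 1.0
        assert np.allclose(eigenvector_centrality(network_from(w)).values, 1.0)

    def test_star_center_strictly_largest(self):
        values = eigenvector_centrality(star_graph(5)).values
        assert values[0] == 1.0
        assert np.all(values[1:] < 1.0)

    def test_matches_dense_eigensolver(self):
        rng = np.random.default_rng(5)
        net = random_network(rng, 8, p=0.9)
        vals, vecs = np.linalg.eigh(net.weights)
        expected = np.abs(vecs[:, -1])
        expected /= expected.max()
        assert np.allclose(eigenvector_centrality(net).values, expected, atol=1e-6)

    def test_disconnected_zeros_off_largest_component(self, caplog):
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
        w[3, 4] = w[4, 3] = 1.0
        with caplog.at_level("WARNING"):
            values = eigenvector_centrality(network_from(w)).values
        assert np.all(values[3:] == 0)
        assert "components" in caplog.text


class TestModularityQ:
    def test_single_module_is_exactly_zero(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            net = random_network(rng, int(rng.integers(3, 12)), p=0.6)
            if net.weights.sum() == 0:
                continue
            assert modularity_Q(net, np.zeros(net.n_nodes, int)) == pytest.approx(0, abs=1e-12)

    def test_two_disconnected_triangles_is_half(self):
        w = np.zeros((6, 6))
        for base in (0, 3):
            for i in range(base, base + 3):
                for j in range(i + 1, base + 3):
                    w[i, j] = w[j, i] = 1.0
        net = network_from(w)
        q = modularity_Q(net, np.array([0, 0, 0, 1, 1, 1]))
        assert q == pytest.approx(0.5)

    def test_matches_double_sum_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            net = random_network(rng, 7, p=0.6)
            if net.weights.sum() == 0:
                continue
            part = rng.integers(0, 3, 7)
            # compact ids for the API; the oracle takes raw labels
            ids = np.unique(part, return_inverse=True)[1]
            assert modularity_Q(net, ids) == pytest.approx(
                brute_modularity(net.weights, part)
            )

    def test_zero_weight_network_rejected(self):
        with pytest.raises(ComputationError):
            modularity_Q(network_from(np.zeros((3, 3))), np.zeros(3, int))


class TestDetectModules:
    def test_twin_cliques_split_exactly(self):
        part = detect_modules(twin_cliques(5), seed=0)
        assert part.n_modules == 2
        assert len(set(part.assignment[:5])) == 1
        assert len(set(part.assignment[5:])) == 1
        assert part.Q == pytest.approx(0.5)

    def test_complete_graph_single_module(self):
        part = detect_modules(complete_graph(8), seed=0)
        assert part.n_modules == 1
        assert part.Q == pytest.approx(0.0, abs=1e-12)

    def test_q_never_negative(self):
        rng = np.random.default_rng(17)
        for seed in range(10):
            net = random_network(rng, 12, p=0.4)
            if net.weights.sum() == 0:
                continue
            assert detect_modules(net, seed=seed).Q >= -1e-12

    def test_exhaustive_bipartition_oracle_small(self):
        """On a 6-node graph with clear 2-module structure the detected Q
        equals the best over all 2^(n-1) bipartitions."""
        rng = np.random.default_rng(3)
        w = np.zeros((6, 6))
        w[:3, :3] = 0.9
        w[3:, 3:] = 0.9
        w[0, 3] = w[3, 0] = 0.1
        np.fill_diagonal(w, 0.0)
        net = network_from(w)
        best = -1.0
        for mask in range(2 ** 5):
            assignment = np.array([0] + [(mask >> i) & 1 for i in range(5)])
            best = max(best, modularity_Q(net, assignment))
        assert detect_modules(net, seed=0).Q == pytest.approx(best)

    def test_seed_only_affects_ties(self):
        net = twin_cliques(4)
        a = detect_modules(net, seed=1).assignment
        b = detect_modules(net, seed=99).assignment
        assert np.array_equal(a, b)


class TestInvariants:
    def test_permutation_equivariance(self):
        rng = np.random.default_rng(21)
        net = random_network(rng, 9, p=0.6)
        perm = rng.permutation(9)
        permuted = bind_matrix(
            net.weights[np.ix_(perm, perm)],
            Ordering(tuple(net.ordering.names[i] for i in perm)),
        )
        for metric in (strength, clustering_coefficient, local_efficiency,
                       betweenness_centrality):
            orig = metric(net).values
            assert np.allclose(metric(permuted).values, orig[perm], atol=1e-9)
        assert global_efficiency(permuted) == pytest.approx(global_efficiency(net))
        assignment = rng.integers(0, 2, 9)
        ids = np.unique(assignment, return_inverse=True)[1]
        assert modularity_Q(permuted, ids[perm]) == pytest.approx(
            modularity_Q(net, ids)
        )

    def test_weighted_reduces_to_binary_on_unit_weights(self):
        rng = np.random.default_rng(23)
        w = (rng.random((10, 10)) < 0.4).astype(float)
        w = np.triu(w, 1)
        net = network_from(w + w.T)
        for metric in (clustering_coefficient, local_efficiency, betweenness_centrality):
            assert np.allclose(
                metric(net, "weighted").values, metric(net, "binary").values
            )
        assert global_efficiency(net, "weighted") == pytest.approx(
            global_efficiency(net, "binary")
        )

    def test_negative_weights_rejected_with_guidance(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = -1.0
        net = network_from(w)
        for fn in (lambda: global_efficiency(net),
                   lambda: detect_modules(net),
                   lambda: modularity_Q(net, np.zeros(3, int))):
            with pytest.raises(ComputationError, match="threshold|absolute"):
                fn()


class TestComputeAll:
    def test_triangle_graph_report(self):
        report = compute_all(complete_graph(3))
        assert np.allclose(report.nodal["strength"].values, 2)
        assert np.allclose(report.nodal["clustering_binary"].values, 1)
        assert report.partition is not None and report.partition.n_modules == 1

    def test_edgeless_graph_records_modularity_error(self):
        report = compute_all(network_from(np.zeros((4, 4))))
        assert np.all(report.nodal["strength"].values == 0)
        assert report.global_scalars["global_efficiency_binary"] == 0.0
        assert "modularity" in report.errors

    def test_report_matches_individual_calls(self, tiny_network):
        report = compute_all(tiny_network, seed=0)
        assert np.allclose(
            report.nodal["strength"].values, strength(tiny_network).values
        )
        assert report.global_scalars["modularity_Q"] == pytest.approx(
            detect_modules(tiny_network, seed=0).Q
        )


class TestModulePartitionType:
    def test_non_contiguous_ids_rejected(self):
        with pytest.raises(Exception, match="contiguous"):
            ModulePartition(np.array([0, 2, 2]), 0.1)
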