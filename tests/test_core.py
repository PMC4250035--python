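"""Network data model: orderings, binding, thresholding, isolation,
registration, and name matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connview.core import (
    AffineRegistration,
    EdgeSet,
    FormatError,
    Ordering,
    ThresholdSpec,
    ValidationError,
    apply_registration,
    bind_matrix,
    canonical_name,
    isolate_node,
    load_matrix,
    match_nodes,
    read_ordering,
    threshold_edges,
)
from connview.io import Parcellation, ParcellationNode

from conftest import names, network_from, random_network


class TestOrdering:
    def test_reads_names_in_file_order(self, tmp_path):
        path = tmp_path / "order.txt"
        path.write_text("lh_precentral\nrh_precentral\nLeft-Hippocampus\n")
        assert read_ordering(path).names == (
            "lh_precentral", "rh_precentral", "Left-Hippocampus",
        )

    def test_skips_blank_and_comment_lines(self, tmp_path):
        path = tmp_path / "order.txt"
        path.write_text("# regions\n a \n\nb\n\n")
        assert read_ordering(path).names == ("a", "b")

    def test_empty_file_is_a_format_error(self, tmp_path):
        path = tmp_path / "order.txt"
        path.write_text("\n\n# only comments\n")
        with pytest.raises(FormatError):
            read_ordering(path)

    def test_duplicate_name_rejected_with_the_duplicate_named(self):
        with pytest.raises(ValidationError, match="'a'"):
            Ordering(("a", "a"))

    def test_unknown_name_lookup_suggests_near_matches(self):
        ordering = Ordering(("lh_frontal", "rh_frontal"))
        with pytest.raises(ValidationError, match="lh_frontal"):
            ordering.index("lh_frontall")


class TestBindMatrix:
    def test_symmetric_matrix_binds_with_zeroed_diagonal(self):
        w = np.array([[5.0, 1, 2], [1, 5, 3], [2, 3, 5]])
        net = bind_matrix(w, names(3))
        assert np.all(np.diag(net.weights) == 0)
        assert net.weights[0, 1] == 1

    def test_symmetrize_averages_with_transpose(self):
        net = bind_matrix(np.array([[0.0, 2], [0, 0]]), names(2), symmetrize=True)
        assert np.allclose(net.weights, [[0, 1], [1, 0]])

    def test_dimension_mismatch_reports_both_sizes(self):
        with pytest.raises(ValidationError, match="3x3.*4"):
            bind_matrix(np.zeros((3, 3)), names(4))

    def test_asymmetric_without_symmetrize_reports_max_deviation(self):
        with pytest.raises(ValidationError, match="2"):
            bind_matrix(np.array([[0.0, 2], [0, 0]]), names(2))

    @pytest.mark.parametrize("suffix", ["txt", "csv", "npy", "mat"])
    def test_load_matrix_roundtrip_all_formats(self, tmp_path, suffix):
        w = np.array([[0.0, 1.25], [1.25, 0.0]])
        path = tmp_path / f"m.{suffix}"
        if suffix == "txt":
            np.savetxt(path, w)
        elif suffix == "csv":
            np.savetxt(path, w, delimiter=",")
        elif suffix == "npy":
            np.save(path, w)
        else:
            import scipy.io

            scipy.io.savemat(path, {"adj": w})
        assert np.allclose(load_matrix(path), w)


class TestThreshold:
    def test_count_mode_keeps_exact_top_k(self):
        w = np.zeros((4, 4))
        w[0, 1] = 3.0
        w[0, 2] = 2.0
        w[1, 2] = 1.0
        w[2, 3] = 0.5
        w = w + w.T
        edges = threshold_edges(network_from(w), ThresholdSpec(k=2))
        assert edges.edges == ((0, 1, 3.0), (0, 2, 2.0))

    def test_fewer_edges_than_k_keeps_all(self):
        rng = np.random.default_rng(0)
        net = random_network(rng, 6, p=0.3)
        nonzero = int(np.count_nonzero(np.triu(net.weights, 1)))
        assert len(threshold_edges(net)) == nonzero

    def test_value_mode_keeps_weights_at_least_v(self):
        w = np.zeros((3, 3))
        w[0, 1] = 1.0
        w[0, 2] = 0.4
        net = network_from(w + w.T)
        edges = threshold_edges(net, ThresholdSpec(mode="value", v=0.5))
        assert edges.pairs() == {(0, 1)}

    def test_proportion_mode_keeps_ceil_fraction(self):
        rng = np.random.default_rng(1)
        net = random_network(rng, 10, p=1.0)
        total = 45
        edges = threshold_edges(net, ThresholdSpec(mode="proportion", p=0.1))
        assert len(edges) == int(np.ceil(0.1 * total))

    def test_absolute_ranking_prefers_large_negative(self):
        w = np.zeros((3, 3))
        w[0, 1] = -2.0
        w[0, 2] = 1.0
        net = network_from(w + w.T)
        signed = threshold_edges(net, ThresholdSpec(k=1, rank_by="signed"))
        absolute = threshold_edges(net, ThresholdSpec(k=1, rank_by="absolute"))
        assert signed.pairs() == {(0, 2)}
        assert absolute.pairs() == {(0, 1)}

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.integers(1, 40))
    def test_count_mode_matches_full_sort_oracle(self, seed, k):
        """Top-k selection equals the first min(k, E) entries of the full
        descending sort over all node pairs."""
        rng = np.random.default_rng(seed)
        net = random_network(rng, int(rng.integers(3, 30)), p=0.5)
        iu, ju = np.triu_indices(net.n_nodes, 1)
        full = [
            (i, j, net.weights[i, j])
            for i, j in zip(iu, ju)
            if net.weights[i, j] != 0
        ]
        full.sort(key=lambda e: (-e[2], e[0], e[1]))
        expected = sorted(full[:k], key=lambda e: (e[0], e[1]))
        got = threshold_edges(net, ThresholdSpec(k=k))
        assert list(got.edges) == [(i, j, pytest.approx(w)) for i, j, w in expected]

    def test_thresholding_is_idempotent(self):
        rng = np.random.default_rng(3)
        net = random_network(rng, 12, p=0.8)
        first = threshold_edges(net, ThresholdSpec(k=20))
        w = np.zeros_like(net.weights)
        for i, j, weight in first:
            w[i, j] = w[j, i] = weight
        again = threshold_edges(network_from(w), ThresholdSpec(k=20))
        assert again.edges == first.edges


class TestIsolateNode:
    def _star(self, leaves=4):
        n = leaves + 1
        w = np.zeros((n, n))
        w[0, 1:] = w[1:, 0] = 1.0
        net = network_from(w)
        return net, threshold_edges(net)

    def test_center_of_star_keeps_all_edges(self):
        net, edges = self._star()
        assert isolate_node(net, edges, 0).pairs() == edges.pairs()

    def test_leaf_keeps_exactly_one_edge(self):
        net, edges = self._star()
        assert len(isolate_node(net, edges, "n3")) == 1

    def test_isolated_node_yields_empty_set(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        net = network_from(w)
        assert len(isolate_node(net, threshold_edges(net), 2)) == 0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_isolation_partitions_each_edge_to_its_two_endpoints(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(rng, int(rng.integers(3, 15)), p=0.5)
        edges = threshold_edges(net)
        counts: dict = {}
        for v in range(net.n_nodes):
            sub = isolate_node(net, edges, v)
            assert sub.pairs() <= edges.pairs()
            for i, j, _w in sub:
                assert v in (i, j)
                counts[(i, j)] = counts.get((i, j), 0) + 1
        assert all(c == 2 for c in counts.values())
        assert set(counts) == edges.pairs()


class TestRegistration:
    def test_identity_is_identity(self):
        reg = AffineRegistration(np.eye(4))
        pts = np.array([[1.0, -2.0, 3.5]])
        assert np.allclose(apply_registration(pts, reg), pts)

    def test_translation_moves_origin(self):
        m = np.eye(4)
        m[:3, 3] = [1, 2, 3]
        out = apply_registration(np.zeros((1, 3)), AffineRegistration(m))
        assert np.allclose(out, [[1, 2, 3]])

    def test_uniform_scale(self):
        m = np.diag([2.0, 2.0, 2.0, 1.0])
        out = apply_registration(np.ones((1, 3)), AffineRegistration(m))
        assert np.allclose(out, [[2, 2, 2]])

    def test_singular_matrix_rejected(self):
        m = np.eye(4)
        m[0, 0] = 0.0
        with pytest.raises(ValidationError, match="invertible"):
            AffineRegistration(m)

    def test_bad_bottom_row_rejected(self):
        m = np.eye(4)
        m[3, 0] = 0.5
        with pytest.raises(ValidationError, match="bottom row"):
            AffineRegistration(m)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_inverse_recovers_inputs(self, seed):
        rng = np.random.default_rng(seed)
        m = np.eye(4)
        m[:3, :3] = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        m[:3, 3] = rng.normal(size=3) * 10
        reg = AffineRegistration(m)
        pts = rng.normal(size=(7, 3)) * 50
        back = apply_registration(apply_registration(pts, reg), reg.inverse())
        assert np.allclose(back, pts, atol=1e-9)


class TestNameMatching:
    @pytest.mark.parametrize(
        "a, b",
        [
            ("lh_precentral", ("lh", "precentral")),
            ("LH.Precentral", ("lh", "precentral")),
            ("precentral-lh", ("lh", "precentral")),
            ("Left-Hippocampus", ("lh", "hippocampus")),
            ("Right-Thalamus-Proper", ("rh", "thalamus_proper")),
            ("brainstem", ("", "brainstem")),
        ],
    )
    def test_canonicalization_table(self, a, b):
        assert canonical_name(a) == b

    def _parcellation(self, *node_names):
        return Parcellation(tuple(
            ParcellationNode(name, (0.0, 0.0, 0.0)) for name in node_names
        ))

    def test_case_insensitive_match(self):
        mapping = match_nodes(Ordering(("lh_a",)), self._parcellation("LH_A"))
        assert mapping == {0: 0}

    def test_suffix_prefix_convention_match(self):
        mapping = match_nodes(Ordering(("a-lh",)), self._parcellation("lh_a"))
        assert mapping == {0: 0}

    def test_unmatched_name_lists_all_unmatched(self):
        with pytest.raises(ValidationError, match=r"lh_a"):
            match_nodes(Ordering(("lh_a", "lh_b")), self._parcellation("lh_b"))

    def test_parcellation_rejects_canonically_colliding_names(self):
        # two spellings of the same region cannot coexist as distinct nodes
        with pytest.raises(ValidationError, match="canonical"):
            self._parcellation("lh_a", "LH_A")


class TestEdgeSet:
    def test_rejects_out_of_range_and_duplicates(self):
        with pytest.raises(ValidationError):
            EdgeSet(((0, 5, 1.0),), source_n=3)
        with pytest.raises(ValidationError):
            EdgeSet(((0, 1, 1.0), (0, 1, 2.0)), source_n=3)
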