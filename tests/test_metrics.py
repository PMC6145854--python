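"""Similarity, network metrics, effect size, cohort analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import streamwarp as sw
from streamwarp.metrics import network_metrics


def _sym(counts):
    """Symmetric zero-diagonal int matrix from an upper-triangle spec."""
    counts = np.asarray(counts, dtype=np.int64)
    return counts + counts.T


def _from_edges(n, edges):
    M = np.zeros((n, n), dtype=np.int64)
    for i, j in edges:
        M[i, j] = M[j, i] = 1
    return M


def _random_matrix(rng, n=6, high=5):
    upper = np.triu(rng.integers(0, high, size=(n, n)), k=1)
    return _sym(upper)


class TestJaccard:
    def test_identical_matrices_have_distance_zero(self):
        M = _from_edges(4, [(0, 1), (2, 3)])
        assert sw.generalized_jaccard_distance(M, M) == 0.0

    def test_disjoint_supports_have_distance_one(self):
        A = _from_edges(4, [(0, 1)])
        B = _from_edges(4, [(2, 3)])
        assert sw.generalized_jaccard_distance(A, B) == 1.0

    def test_printed_formula_hand_case(self):
        # upper triangles (2, 0, 3) vs (1, 1, 3): 1 - 4/6
        A = np.zeros((3, 3), dtype=np.int64)
        A[0, 1], A[0, 2], A[1, 2] = 2, 0, 3
        B = np.zeros((3, 3), dtype=np.int64)
        B[0, 1], B[0, 2], B[1, 2] = 1, 1, 3
        d = sw.generalized_jaccard_distance(_sym(A), _sym(B))
        assert d == pytest.approx(1.0 - 4.0 / 6.0, abs=1e-12)

    def test_all_zero_pair_is_undefined(self):
        Z = np.zeros((3, 3), dtype=np.int64)
        with pytest.raises(sw.StreamwarpError):
            sw.generalized_jaccard_distance(Z, Z)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(sw.StreamwarpError):
            sw.generalized_jaccard_distance(np.zeros((3, 3), dtype=int),
                                            np.ones((4, 4), dtype=int))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_metric_axioms_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        A, B, C = (_random_matrix(rng) for _ in range(3))
        if not (A.any() or B.any()) or not (B.any() or C.any()) \
                or not (A.any() or C.any()):
            return
        dab = sw.generalized_jaccard_distance(A, B)
        dba = sw.generalized_jaccard_distance(B, A)
        dac = sw.generalized_jaccard_distance(A, C)
        dcb = sw.generalized_jaccard_distance(C, B)
        assert 0.0 <= dab <= 1.0
        assert dab == dba
        assert dab <= dac + dcb + 1e-12


class TestGraphMetrics:
    def test_average_degree_examples(self):
        assert sw.average_degree(_from_edges(4, [(0, 1), (1, 2), (2, 3)])) == 1.5
        assert sw.average_degree(np.zeros((5, 5), dtype=int)) == 0.0
        complete = _sym(np.triu(np.ones((5, 5), dtype=int), k=1))
        assert sw.average_degree(complete) == 4.0

    def test_density_examples(self):
        assert sw.density(_from_edges(4, [(0, 1), (1, 2), (2, 3)])) == 0.5
        complete = _sym(np.triu(np.ones((5, 5), dtype=int), k=1))
        assert sw.density(complete) == 1.0
        assert sw.density(np.zeros((4, 4), dtype=int)) == 0.0
        with pytest.raises(sw.StreamwarpError):
            sw.density(np.zeros((1, 1), dtype=int))

    def test_star_graph_is_perfectly_disassortative(self):
        star = _from_edges(4, [(0, 1), (0, 2), (0, 3)])
        assert sw.assortativity(star) == pytest.approx(-1.0, abs=1e-12)

    def test_path_graph_is_perfectly_disassortative(self):
        path = _from_edges(3, [(0, 1), (1, 2)])
        assert sw.assortativity(path) == pytest.approx(-1.0, abs=1e-12)

    def test_regular_ring_is_undefined(self):
        ring = _from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        assert sw.assortativity(ring) is None
        assert network_metrics(ring).assortativity_defined is False

    def test_edgeless_graph_raises(self):
        with pytest.raises(sw.StreamwarpError):
            sw.assortativity(np.zeros((3, 3), dtype=int))

    def test_assortativity_matches_networkx(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 20:
            M = _random_matrix(rng, n=8, high=2)
            a = sw.assortativity(M) if M.any() else None
            if a is None:
                continue
            g = nx.from_numpy_array(M != 0)
            assert a == pytest.approx(
                nx.degree_assortativity_coefficient(g), abs=1e-9)
            checked += 1

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_degree_density_identity_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        M = _random_matrix(rng, n=n, high=3)
        k = sw.average_degree(M)
        d = sw.density(M)
        assert k == pytest.approx((n - 1) * d, abs=1e-13)
        if M.any():
            a = sw.assortativity(M)
            if a is not None:
                assert -1.0 - 1e-9 <= a <= 1.0 + 1e-9

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_metrics_invariant_under_node_permutation(self, seed):
        rng = np.random.default_rng(seed)
        M = _random_matrix(rng, n=7)
        if not M.any():
            return
        perm = rng.permutation(7)
        P = M[np.ix_(perm, perm)]
        assert sw.average_degree(M) == sw.average_degree(P)
        assert sw.density(M) == sw.density(P)
        a, b = sw.assortativity(M), sw.assortativity(P)
        if a is None:
            assert b is None
        else:
            assert a == pytest.approx(b, abs=1e-12)


class TestGlassDelta:
    def test_identical_groups_give_zero(self):
        assert sw.glass_delta([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_computed_case(self):
        # native (0, 2): mean 1, sample sd sqrt(2); template mean 0
        assert sw.glass_delta([0.0, 2.0], [0.0]) == pytest.approx(
            1.0 / np.sqrt(2.0), abs=1e-12)

    def test_sign_follows_mean_difference(self):
        assert sw.glass_delta([0.0, 2.0], [5.0, 5.0]) < 0

    def test_zero_native_variance_is_undefined(self):
        with pytest.raises(sw.StreamwarpError):
            sw.glass_delta([1.0, 1.0], [2.0])


class TestCohort:
    def _matrix(self, rng, base=None, noise=0):
        M = _random_matrix(rng, n=6, high=8) if base is None else base.copy()
        if noise:
            upper = np.triu(rng.integers(0, noise + 1, size=M.shape), k=1)
            M = M + _sym(upper)
        return sw.ConnectivityMatrix(M, np.arange(1, 7))

    def test_identical_subjects_have_zero_distance_everywhere(self):
        rng = np.random.default_rng(0)
        M = self._matrix(rng)
        mats = {"s1": M, "s2": M, "s3": M, "s4": M}
        _, summary = sw.cohort_pairwise_analysis(
            mats, [("s1", "s2", "identical"), ("s3", "s4", "unrelated")])
        assert (summary["distance_mean"] == 0.0).all()

    def test_duplicated_pairs_with_varying_metrics_correlate_perfectly(self):
        rng = np.random.default_rng(1)
        pairs, mats = [], {}
        for i in range(4):
            M = self._matrix(rng)
            mats[f"a{i}"] = mats[f"b{i}"] = M
            pairs.append((f"a{i}", f"b{i}", "identical"))
        _, summary = sw.cohort_pairwise_analysis(mats, pairs)
        row = summary.set_index("pair_type").loc["identical"]
        assert row["density_r"] == pytest.approx(1.0, abs=1e-12)
        assert row["density_r2"] == pytest.approx(1.0, abs=1e-12)

    def test_twin_like_cohort_orders_group_distances(self):
        # "identical twins" share a base matrix plus small noise;
        # "unrelated" pairs are independent draws
        rng = np.random.default_rng(2)
        mats, pairs = {}, []
        for i in range(10):
            base = _random_matrix(rng, n=6, high=20)
            mats[f"t{i}a"] = self._matrix(rng, base, noise=1)
            mats[f"t{i}b"] = self._matrix(rng, base, noise=1)
            pairs.append((f"t{i}a", f"t{i}b", "identical"))
        for i in range(10):
            mats[f"u{i}a"] = self._matrix(rng)
            mats[f"u{i}b"] = self._matrix(rng)
            pairs.append((f"u{i}a", f"u{i}b", "unrelated"))
        _, summary = sw.cohort_pairwise_analysis(mats, pairs)
        s = summary.set_index("pair_type")
        assert s.loc["identical", "distance_mean"] < \
            s.loc["unrelated", "distance_mean"]

    def test_unknown_subject_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(sw.StreamwarpError, match="ghost"):
            sw.cohort_pairwise_analysis({"a": self._matrix(rng)},
                                        [("a", "ghost", "unrelated")])

    def test_single_pair_group_leaves_correlation_undefined(self):
        rng = np.random.default_rng(4)
        mats = {"a": self._matrix(rng), "b": self._matrix(rng)}
        _, summary = sw.cohort_pairwise_analysis(mats, [("a", "b", "solo")])
        assert np.isnan(summary.loc[0, "density_r"])
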