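"""Self-organized adjacency, sparsification, Laplacian and spectral filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sognn.graphs import (
    average_adjacency,
    correlation_graph,
    covariance_graph,
    extract_diagonal,
    load_adjacency_csv,
    minmax_normalize,
    normalized_laplacian,
    save_adjacency_csv,
    self_organized_adjacency,
    spectral_graph_conv,
    topk_sparsify,
)


def adjacency_loop_oracle(V, W):
    """Brute-force elementwise evaluation: exp of bottleneck inner products,
    normalized row by row with explicit Python loops."""
    G = np.tanh(V @ W)
    n = G.shape[0]
    A = np.zeros((n, n))
    for i in range(n):
        row = np.array([np.exp(G[i] @ G[j]) for j in range(n)])
        A[i] = row / row.sum()
    return A


class TestSelfOrganizedAdjacency:
    def test_identical_rows_give_uniform_weights(self):
        V = np.tile(np.array([1.0, -0.5, 2.0]), (6, 1))
        W = np.random.default_rng(0).normal(size=(3, 4))
        A = self_organized_adjacency(V, W)
        assert np.array_equal(A, np.full((6, 6), 1 / 6))

    def test_full_montage_rows_sum_to_one(self, rng):
        V = rng.normal(size=(62, 20))
        W = rng.normal(size=(20, 64))
        A = self_organized_adjacency(V, W)
        assert A.shape == (62, 62)
        assert np.all(A >= 0)
        assert np.allclose(A.sum(axis=1), 1.0, atol=1e-6)

    def test_matches_elementwise_loop_oracle(self, rng):
        V = rng.normal(size=(4, 3))
        W = rng.normal(size=(3, 5))
        A = self_organized_adjacency(V, W)
        assert np.allclose(A, adjacency_loop_oracle(V, W), atol=1e-10)

    def test_permutation_equivariance(self, rng):
        V = rng.normal(size=(7, 4))
        W = rng.normal(size=(4, 6))
        perm = rng.permutation(7)
        A = self_organized_adjacency(V, W)
        A_perm = self_organized_adjacency(V[perm], W)
        assert np.allclose(A_perm, A[np.ix_(perm, perm)], atol=1e-12)

    def test_nonfinite_features_rejected(self):
        V = np.ones((3, 2))
        V[1, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            self_organized_adjacency(V, np.ones((2, 2)))

    @given(
        st.integers(2, 8), st.integers(1, 5), st.integers(1, 6),
        st.integers(0, 2**31 - 1),
    )
    @settings(deadline=None, max_examples=40)
    def test_row_sums_conserved_for_any_input(self, n, f, ell, seed):
        r = np.random.default_rng(seed)
        A = self_organized_adjacency(r.normal(size=(n, f)), r.normal(size=(f, ell)))
        assert np.allclose(A.sum(axis=1), 1.0, atol=1e-9)


class TestTopkSparsify:
    def test_k_equal_to_montage_size_is_identity(self, rng):
        A = rng.uniform(size=(62, 62))
        assert np.array_equal(topk_sparsify(A, 62), A)

    def test_k_beyond_n_is_identity(self, rng):
        A = rng.uniform(size=(5, 5))
        assert np.array_equal(topk_sparsify(A, 9), A)

    def test_matches_full_sort_oracle(self, rng):
        A = rng.uniform(size=(5, 5))
        sparse = topk_sparsify(A, 2)
        for i in range(5):
            expected = sorted(np.argsort(-A[i])[:2])
            assert sorted(np.flatnonzero(sparse[i])) == expected
            assert np.array_equal(sparse[i][expected], A[i][expected])

    def test_retained_values_unchanged(self, rng):
        A = rng.uniform(size=(6, 6))
        sparse = topk_sparsify(A, 3)
        kept = sparse != 0
        assert np.array_equal(sparse[kept], A[kept])
        assert np.all(kept.sum(axis=1) == 3)

    def test_idempotent(self, rng):
        A = rng.uniform(size=(8, 8))
        once = topk_sparsify(A, 4)
        assert np.array_equal(topk_sparsify(once, 4), once)

    def test_ties_break_toward_lower_index(self):
        A = np.array([[1.0, 1.0, 1.0, 0.5]])
        sparse = topk_sparsify(A, 2)
        assert np.array_equal(np.flatnonzero(sparse[0]), [0, 1])

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError, match="k must be"):
            topk_sparsify(np.ones((3, 3)), 0)


class TestBaselineGraphs:
    def test_proportional_rows_perfectly_correlated(self):
        V = np.vstack([np.arange(10.0), 3 * np.arange(10.0) + 1])
        C = correlation_graph(V)
        assert C[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(C), 1.0)

    def test_independent_noise_rows_weakly_correlated(self):
        V = np.random.default_rng(5).normal(size=(6, 1000))
        C = correlation_graph(V)
        off = C[~np.eye(6, dtype=bool)]
        assert np.all(off < 0.15)

    def test_correlation_entries_bounded(self, rng):
        C = correlation_graph(rng.normal(size=(8, 40)))
        assert np.all((C >= 0) & (C <= 1))

    def test_covariance_matches_numpy_definition(self, rng):
        V = rng.normal(size=(5, 30))
        assert np.allclose(covariance_graph(V), np.cov(V))

    def test_zero_variance_row_rejected(self):
        V = np.vstack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="zero variance"):
            correlation_graph(V)


def laplacian_definitional_oracle(A_sym):
    D = np.diag(A_sym.sum(axis=1))
    d_inv_sqrt = np.diag(1 / np.sqrt(np.diag(D)))
    return np.eye(len(A_sym)) - d_inv_sqrt @ A_sym @ d_inv_sqrt


class TestNormalizedLaplacian:
    def test_identity_adjacency_gives_zero_laplacian(self):
        assert np.allclose(normalized_laplacian(np.eye(5)), 0.0, atol=1e-12)

    def test_complete_graph_spectrum(self):
        A = np.ones((4, 4)) - np.eye(4)
        eig = np.sort(np.linalg.eigvalsh(normalized_laplacian(A)))
        assert np.allclose(eig, [0.0, 4 / 3, 4 / 3, 4 / 3], atol=1e-10)

    def test_matches_definitional_oracle(self, rng):
        A = rng.uniform(size=(8, 8))
        A = 0.5 * (A + A.T)
        assert np.allclose(normalized_laplacian(A), laplacian_definitional_oracle(A), atol=1e-10)

    @given(st.integers(2, 10), st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=40)
    def test_spectrum_always_in_zero_two(self, n, seed):
        A = np.random.default_rng(seed).uniform(0.01, 1.0, size=(n, n))
        eig = np.linalg.eigvalsh(normalized_laplacian(A))
        assert eig.min() > -1e-8
        assert eig.max() < 2 + 1e-8

    def test_isolated_node_raises_by_default(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 1.0
        with pytest.raises(ValueError, match="isolated node"):
            normalized_laplacian(A)

    def test_isolated_node_self_loop_fallback(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 1.0
        L = normalized_laplacian(A, isolated="self-loop")
        assert L.shape == (3, 3)
        assert np.allclose(L[2], [0, 0, 0])  # unit self-loop: degree 1, L_ii = 1-1

    def test_negative_adjacency_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            normalized_laplacian(-np.ones((2, 2)))


class TestSpectralGraphConv:
    def random_graph(self, rng, n):
        A = rng.uniform(0.05, 1.0, size=(n, n))
        return normalized_laplacian(A)

    def test_identity_filter_passes_input_through(self, rng):
        n, c = 6, 4
        L = self.random_graph(rng, n)
        X = rng.normal(size=(n, c))
        coeff = np.zeros((3, c, c))
        coeff[0] = np.eye(c)
        assert np.array_equal(spectral_graph_conv(X, L, coeff), X)

    def test_zero_filter_gives_zero(self, rng):
        L = self.random_graph(rng, 5)
        X = rng.normal(size=(5, 3))
        out = spectral_graph_conv(X, L, np.zeros((3, 3, 2)))
        assert np.all(out == 0)
        assert out.shape == (5, 2)

    def test_recurrence_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(11)
        worst = 0.0
        for _ in range(100):
            n = int(rng.integers(3, 11))
            L = self.random_graph(rng, n)
            X = rng.normal(size=(n, int(rng.integers(1, 5))))
            coeff = rng.normal(size=(3, X.shape[1], int(rng.integers(1, 5))))
            fast = spectral_graph_conv(X, L, coeff, method="recurrence")
            ref = spectral_graph_conv(X, L, coeff, method="eigh")
            worst = max(worst, np.abs(fast - ref).max() / max(np.abs(ref).max(), 1e-12))
        assert worst < 1e-5

    def test_shape_mismatch_rejected(self, rng):
        L = self.random_graph(rng, 4)
        with pytest.raises(ValueError, match="incompatible"):
            spectral_graph_conv(rng.normal(size=(5, 2)), L, np.zeros((3, 2, 2)))


class TestAdjacencySummaries:
    def test_average_of_identical_matrices_is_identity_operation(self, rng):
        A = rng.uniform(size=(4, 4))
        assert np.array_equal(average_adjacency([A, A]), A)

    def test_minmax_affine_rescale(self):
        A = np.array([[2.0, 3.0], [4.0, 2.5]])
        out = minmax_normalize(A)
        assert np.allclose(out, (A - 2) / 2)
        assert out.min() == 0.0
        assert out.max() == 1.0

    def test_minmax_of_constant_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="constant"):
            out = minmax_normalize(np.full((3, 3), 7.0))
        assert np.all(out == 0)

    def test_diagonal_of_identity(self):
        assert np.array_equal(extract_diagonal(np.eye(4)), np.ones(4))

    def test_diagonal_with_channel_labels(self):
        pairs = extract_diagonal(np.diag([0.5, 0.25]), ["FP1", "CPZ"])
        assert pairs == [("FP1", 0.5), ("CPZ", 0.25)]

    def test_csv_round_trip_bit_exact(self, rng, tmp_path):
        A = rng.normal(size=(5, 5))
        names = [f"E{i}" for i in range(5)]
        save_adjacency_csv(tmp_path / "a.csv", A, names)
        B, loaded_names = load_adjacency_csv(tmp_path / "a.csv")
        assert loaded_names == names
        assert np.array_equal(A, B)
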