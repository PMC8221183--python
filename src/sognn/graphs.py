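"""Per-sample graph construction and spectral graph convolution.

The self-organized adjacency maps node features V (one row per electrode)
through a tanh bottleneck G = tanh(V W) and row-softmaxes the Gram matrix
G G^T, giving a dense, nonnegative adjacency whose rows sum to one.  Top-k
sparsification keeps the k largest weights per row.  Spectral filtering uses
the symmetric normalized Laplacian L = I - D^{-1/2} A D^{-1/2} and an
order-K Chebyshev polynomial filter, evaluated either by the vertex-domain
three-term recurrence (the fast path) or through the explicit
eigendecomposition U Theta(Lambda) U^T (the reference path).

Functions here are plain numpy and operate on single samples; the trainable
batched counterparts live in :mod:`sognn.model` and are tested to agree with
these.
"""

from __future__ import annotations

import csv
import warnings

import numpy as np

__all__ = [
    "self_organized_adjacency",
    "topk_sparsify",
    "covariance_graph",
    "correlation_graph",
    "normalized_laplacian",
    "chebyshev_coefficients_shape",
    "spectral_graph_conv",
    "average_adjacency",
    "minmax_normalize",
    "extract_diagonal",
    "save_adjacency_csv",
    "load_adjacency_csv",
]


def _row_softmax(s: np.ndarray) -> np.ndarray:
    z = s - s.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def self_organized_adjacency(V: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Dense self-organized adjacency A = row_softmax(tanh(VW) tanh(VW)^T)."""
    V = np.asarray(V, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if not np.all(np.isfinite(V)):
        raise ValueError("node features contain non-finite values")
    if V.ndim != 2 or W.ndim != 2 or V.shape[1] != W.shape[0]:
        raise ValueError(f"shape mismatch: V {V.shape} vs W {W.shape}")
    G = np.tanh(V @ W)
    return _row_softmax(G @ G.T)


def topk_sparsify(A: np.ndarray, k: int) -> np.ndarray:
    """Keep the ``min(k, N)`` largest entries of each row, zero the rest.

    Ties break toward the lower column index (stable selection), so the
    result is deterministic.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    A = np.asarray(A, dtype=np.float64)
    n = A.shape[-1]
    k = min(k, n)
    order = np.argsort(-A, axis=-1, kind="stable")
    mask = np.zeros_like(A)
    np.put_along_axis(mask, order[..., :k], 1.0, axis=-1)
    return A * mask


def covariance_graph(V: np.ndarray) -> np.ndarray:
    """Sample covariance of electrode feature rows (features as observations)."""
    V = np.asarray(V, dtype=np.float64)
    if V.shape[1] < 2:
        raise ValueError("need at least 2 feature columns for covariance")
    _check_row_variance(V)
    return np.cov(V)


def correlation_graph(V: np.ndarray) -> np.ndarray:
    """Absolute Pearson correlation between electrode rows; entries in [0, 1]."""
    V = np.asarray(V, dtype=np.float64)
    if V.shape[1] < 2:
        raise ValueError("need at least 2 feature columns for correlation")
    _check_row_variance(V)
    return np.abs(np.corrcoef(V))


def _check_row_variance(V: np.ndarray) -> None:
    var = V.var(axis=1)
    bad = np.flatnonzero(var == 0)
    if bad.size:
        raise ValueError(f"zero variance in electrode row(s) {bad.tolist()}")


def normalized_laplacian(
    A: np.ndarray, isolated: str = "error"
) -> np.ndarray:
    """Symmetric normalized Laplacian L = I - D^{-1/2} A_sym D^{-1/2}.

    The input is symmetrized as (A + A^T)/2 first (row-softmax plus top-k
    produces asymmetric matrices, but a real symmetric eigensystem is
    required).  ``isolated`` controls zero-degree nodes: ``"error"`` raises,
    ``"self-loop"`` adds a unit self-loop to the offending nodes.
    """
    A = np.asarray(A, dtype=np.float64)
    if np.any(A < 0):
        raise ValueError("adjacency must be nonnegative")
    A_sym = 0.5 * (A + A.T)
    deg = A_sym.sum(axis=1)
    zero = np.flatnonzero(deg == 0)
    if zero.size:
        if isolated == "self-loop":
            A_sym = A_sym.copy()
            A_sym[zero, zero] += 1.0
            deg = A_sym.sum(axis=1)
        else:
            raise ValueError(f"isolated node(s) {zero.tolist()} have zero degree")
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    L = np.eye(A.shape[0]) - d_inv_sqrt[:, None] * A_sym * d_inv_sqrt[None, :]
    return 0.5 * (L + L.T)  # kill rounding asymmetry


def chebyshev_coefficients_shape(order: int, c_in: int, c_out: int) -> tuple[int, int, int]:
    return (order + 1, c_in, c_out)


def spectral_graph_conv(
    X: np.ndarray,
    L: np.ndarray,
    coefficients: np.ndarray,
    lmax: float = 2.0,
    method: str = "recurrence",
) -> np.ndarray:
    """Order-K Chebyshev spectral filter of a multichannel graph signal.

    X is N x C_in, L the normalized Laplacian, ``coefficients`` shaped
    (K+1, C_in, C_out).  The filter acts on the rescaled Laplacian
    Ltilde = 2 L / lmax - I so its spectrum lies in [-1, 1].

    method="recurrence" uses the vertex-domain three-term Chebyshev
    recurrence; method="eigh" evaluates the explicit spectral form
    U Theta(Lambda) U^T X.  Both agree to ~1e-12; the eigh path exists as
    the independent reference.
    """
    X = np.asarray(X, dtype=np.float64)
    L = np.asarray(L, dtype=np.float64)
    coefficients = np.asarray(coefficients, dtype=np.float64)
    n = L.shape[0]
    if X.ndim != 2 or X.shape[0] != n:
        raise ValueError(f"signal shape {X.shape} incompatible with {n}-node Laplacian")
    if coefficients.ndim != 3 or coefficients.shape[1] != X.shape[1]:
        raise ValueError(
            f"coefficients shape {coefficients.shape} incompatible with C_in={X.shape[1]}"
        )
    K = coefficients.shape[0] - 1
    if method == "recurrence":
        Lt = (2.0 / lmax) * L - np.eye(n)
        Tk_prev = X
        out = Tk_prev @ coefficients[0]
        if K >= 1:
            Tk = Lt @ X
            out = out + Tk @ coefficients[1]
            for k in range(2, K + 1):
                Tk, Tk_prev = 2.0 * (Lt @ Tk) - Tk_prev, Tk
                out = out + Tk @ coefficients[k]
        return out
    if method == "eigh":
        lam, U = np.linalg.eigh(L)
        lam_t = (2.0 / lmax) * lam - 1.0
        # Chebyshev polynomials of the rescaled eigenvalues
        T = np.empty((K + 1, n))
        T[0] = 1.0
        if K >= 1:
            T[1] = lam_t
            for k in range(2, K + 1):
                T[k] = 2.0 * lam_t * T[k - 1] - T[k - 2]
        Xhat = U.T @ X  # spectral-domain signal
        out = np.zeros((n, coefficients.shape[2]))
        for k in range(K + 1):
            out += U @ (T[k][:, None] * (Xhat @ coefficients[k]))
        return out
    raise ValueError(f"unknown method {method!r}")


def average_adjacency(samples: list[np.ndarray]) -> np.ndarray:
    """Elementwise mean of a non-empty list of equally shaped adjacencies."""
    if not samples:
        raise ValueError("empty adjacency list")
    return np.mean(np.stack([np.asarray(a, dtype=np.float64) for a in samples]), axis=0)


def minmax_normalize(A: np.ndarray) -> np.ndarray:
    """Affine rescale to [0, 1]; a constant matrix maps to all zeros."""
    A = np.asarray(A, dtype=np.float64)
    lo, hi = A.min(), A.max()
    if hi == lo:
        warnings.warn("constant adjacency in min-max normalization; returning zeros")
        return np.zeros_like(A)
    return (A - lo) / (hi - lo)


def extract_diagonal(A: np.ndarray, channel_names: list[str] | None = None):
    """Diagonal weights in electrode order; with names, as (name, value) pairs."""
    d = np.diag(np.asarray(A, dtype=np.float64)).copy()
    if channel_names is None:
        return d
    if len(channel_names) != d.size:
        raise ValueError("channel name count does not match adjacency size")
    return list(zip(channel_names, d.tolist()))


def save_adjacency_csv(path, A: np.ndarray, channel_names: list[str]) -> None:
    """Dense CSV with channel labels as header row and first column."""
    A = np.asarray(A, dtype=np.float64)
    if A.shape != (len(channel_names), len(channel_names)):
        raise ValueError("adjacency shape does not match channel names")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([""] + list(channel_names))
        for name, row in zip(channel_names, A):
            w.writerow([name] + [repr(float(v)) for v in row])


def load_adjacency_csv(path) -> tuple[np.ndarray, list[str]]:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    names = rows[0][1:]
    A = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
    return A, names
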