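"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the network needs: broadcast arithmetic,
(batched) matmul, tanh/relu/exp/log, reductions, reshapes, row-softmax,
2-D convolution and max-pooling, a straight-through top-k row mask, clamping
and dropout.  Everything is float64; graphs are built eagerly and freed after
``backward``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "maxpool2d", "softmax", "topk_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _backward=None, _parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = _backward
        self._parents = _parents

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [t]
            order = []
            while stack:
                node = stack.pop()
                if id(node) in seen:
                    continue
                seen.add(id(node))
                order.append(node)
                stack.extend(node._parents)
            # order is a DFS pre-order; re-sort topologically below
            topo.extend(order)

        visit(self)
        # Kahn-style topological order by dependency depth
        depth: dict[int, int] = {}

        def get_depth(t: Tensor) -> int:
            d = depth.get(id(t))
            if d is not None:
                return d
            d = 1 + max((get_depth(p) for p in t._parents), default=0)
            depth[id(t)] = d
            return d

        import sys

        old_limit = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old_limit, 10 * len(topo) + 1000))
        try:
            topo.sort(key=get_depth, reverse=True)
        finally:
            sys.setrecursionlimit(old_limit)

        self._accumulate(grad)
        for node in topo:
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free the closure to release memory
            node._backward = None
            node._parents = ()

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
        )

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward, out._parents = bw, (self, other)
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad)

        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward, out._parents = bw, (self,)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
        )

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward, out._parents = bw, (self, other)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(
            self.data / other.data,
            self.requires_grad or other.requires_grad,
        )

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward, out._parents = bw, (self, other)
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, self.requires_grad)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward, out._parents = bw, (self,)
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(
            self.data @ other.data,
            self.requires_grad or other.requires_grad,
        )

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward, out._parents = bw, (self, other)
        return out

    # -- elementwise nonlinearities --------------------------------------

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, self.requires_grad)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - y**2))

        out._backward, out._parents = bw, (self,)
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))

        out._backward, out._parents = bw, (self,)
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, self.requires_grad)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * y)

        out._backward, out._parents = bw, (self,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward, out._parents = bw, (self,)
        return out

    def clamp(self, lo: float, hi: float):
        """Clip values; gradient passes only where input was inside [lo, hi]."""
        out = Tensor(np.clip(self.data, lo, hi), self.requires_grad)
        inside = (self.data >= lo) & (self.data <= hi)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * inside)

        out._backward, out._parents = bw, (self,)
        return out

    # -- reductions & shape ops ------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad)

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward, out._parents = bw, (self,)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        out._backward, out._parents = bw, (self,)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes), self.requires_grad)
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward, out._parents = bw, (self,)
        return out

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), any(t.requires_grad for t in tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    out._backward, out._parents = bw, tuple(tensors)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, x.requires_grad)

    def bw(g):
        if x.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accumulate(s * (g - dot))

    out._backward, out._parents = bw, (x,)
    return out


def topk_rows(x: Tensor, k: int) -> Tensor:
    """Keep the k largest entries along the last axis, zero the rest.

    Gradients pass straight through the retained entries and are blocked at
    the zeroed ones (a modified max-pooling, so training proceeds as with
    ordinary pooling layers).  Ties break toward the lower index.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n = x.shape[-1]
    k = min(k, n)
    # stable descending argsort: equal values keep lower index first
    order = np.argsort(-x.data, axis=-1, kind="stable")
    keep = order[..., :k]
    mask = np.zeros_like(x.data)
    np.put_along_axis(mask, keep, 1.0, axis=-1)
    out = Tensor(x.data * mask, x.requires_grad)

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    out._backward, out._parents = bw, (x,)
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Valid (no padding), stride-1 2-D convolution.

    x: (B, C_in, H, W); w: (C_out, C_in, kh, kw); b: (C_out,) or None.
    """
    B, C, H, W = x.shape
    O, C2, kh, kw = w.shape
    if C != C2:
        raise ValueError(f"channel mismatch: input {C} vs kernel {C2}")
    Ho, Wo = H - kh + 1, W - kw + 1
    if Ho < 1 or Wo < 1:
        raise ValueError(f"kernel ({kh},{kw}) larger than input ({H},{W})")
    win = np.lib.stride_tricks.sliding_window_view(x.data, (kh, kw), axis=(2, 3))
    # win: (B, C, Ho, Wo, kh, kw) -> cols (B*Ho*Wo, C*kh*kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * kh * kw)
    wmat = w.data.reshape(O, C * kh * kw)
    y = cols @ wmat.T
    if b is not None:
        y = y + b.data
    out_data = y.reshape(B, Ho, Wo, O).transpose(0, 3, 1, 2)
    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    out = Tensor(out_data, req)

    def bw(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, O)
        if w.requires_grad:
            w._accumulate((gmat.T @ cols).reshape(O, C, kh, kw))
        if b is not None and b.requires_grad:
            b._accumulate(gmat.sum(axis=0))
        if x.requires_grad:
            gcols = (gmat @ wmat).reshape(B, Ho, Wo, C, kh, kw)
            gx = np.zeros_like(x.data)
            for i in range(kh):
                for j in range(kw):
                    gx[:, :, i : i + Ho, j : j + Wo] += gcols[:, :, :, :, i, j].transpose(
                        0, 3, 1, 2
                    )
            x._accumulate(gx)

    out._backward, out._parents = bw, (x, w) if b is None else (x, w, b)
    return out


def maxpool2d(x: Tensor, pool: tuple[int, int]) -> Tensor:
    """Non-overlapping max pooling with floor-mode edge cropping."""
    ph, pw = pool
    B, C, H, W = x.shape
    Ho, Wo = H // ph, W // pw
    if Ho < 1 or Wo < 1:
        raise ValueError(f"pool {pool} larger than input ({H},{W})")
    crop = x.data[:, :, : Ho * ph, : Wo * pw]
    r = crop.reshape(B, C, Ho, ph, Wo, pw)
    m = r.max(axis=(3, 5))
    out = Tensor(m, x.requires_grad)
    # gradient mask; ties share the gradient equally
    is_max = r == m[:, :, :, None, :, None]
    counts = is_max.sum(axis=(3, 5), keepdims=True)
    mask = is_max / counts

    def bw(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gr = mask * g[:, :, :, None, :, None]
            gx[:, :, : Ho * ph, : Wo * pw] = gr.reshape(B, C, Ho * ph, Wo * pw)
            x._accumulate(gx)

    out._backward, out._parents = bw, (x,)
    return out
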