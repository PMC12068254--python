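"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the wall-motion network needs: broadcasted
arithmetic, matrix multiplication, 1-D same-padded convolution, pointwise
nonlinearities, reductions, slicing, concatenation/stacking and a numerically
stable softmax.  Gradients are float64 and accumulated lazily (a node's grad
buffer is allocated on first contribution), which keeps the backward pass
cheap on graphs with thousands of nodes.  Correctness is established by
finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as _expit

__all__ = ["Tensor", "concat", "stack", "softmax", "conv1d_same", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward

    # -- introspection ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape})"

    # -- gradient accumulation -------------------------------------------
    def _acc(self, g):
        """Add a gradient contribution (allocates the buffer on first use)."""
        if self.grad is None:
            if getattr(g, "shape", None) == self.data.shape:
                self.grad = np.array(g, dtype=np.float64)
            else:
                self.grad = np.array(
                    np.broadcast_to(g, self.data.shape), dtype=np.float64
                )
        else:
            self.grad += g

    def _acc_at(self, idx, g, basic: bool):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        if basic:  # basic slices never alias, so accumulate in place
            self.grad[idx] += g
        else:
            np.add.at(self.grad, idx, g)

    # -- graph traversal -------------------------------------------------
    def backward(self, grad=None):
        """Backpropagate from this node (scalar unless `grad` is given)."""
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = None
        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        )
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ------------------------------------------------------
    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw(g):
            self._acc(_unbroadcast(g, self.data.shape))
            other._acc(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self._acc(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw(g):
            self._acc(_unbroadcast(g * other.data, self.data.shape))
            other._acc(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, (self, other))

        def bw(g):
            self._acc(_unbroadcast(g / other.data, self.data.shape))
            other._acc(
                _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
            )

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bw(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.outer(g, b)
            gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.outer(a, g)
            self._acc(_unbroadcast(ga, a.shape))
            other._acc(_unbroadcast(gb, b.shape))

        out._backward = bw
        return out

    # -- pointwise nonlinearities ----------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), (self,))
        out._backward = lambda g: self._acc(g * out.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), (self,))
        out._backward = lambda g: self._acc(g * (1.0 - out.data**2))
        return out

    def sigmoid(self):
        out = Tensor(_expit(self.data), (self,))
        out._backward = lambda g: self._acc(g * out.data * (1.0 - out.data))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), (self,))
        out._backward = lambda g: self._acc(g * (self.data > 0))
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), (self,))
        out._backward = lambda g: self._acc(g * 0.5 / out.data)
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), (self,))
        out._backward = lambda g: self._acc(g * np.sign(self.data))
        return out

    def minimum(self, cap: float):
        """Elementwise min with a scalar cap (subgradient 0 at the cap)."""
        out = Tensor(np.minimum(self.data, cap), (self,))
        out._backward = lambda g: self._acc(g * (self.data < cap))
        return out

    # -- reductions and reshaping ----------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._acc(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._acc(g.reshape(self.data.shape))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))
        basic = isinstance(idx, (int, slice)) or (
            isinstance(idx, tuple) and all(isinstance(i, (int, slice)) for i in idx)
        )
        out._backward = lambda g: self._acc_at(idx, g, basic)
        return out


def concat(tensors, axis=0):
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._acc(g[tuple(sl)])

    out._backward = bw
    return out


def stack(tensors, axis=0):
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            t._acc(np.take(g, i, axis=axis))

    out._backward = bw
    return out


def softmax(x: Tensor, axis=-1) -> Tensor:
    """Numerically stable softmax; the max shift is treated as a constant."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def conv1d_same(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """1-D convolution, stride 1, edge-replicating same-padding.

    x: (B, T, C), w: (K, C, F) with K odd, b: (F,). Returns (B, T, F).
    Edge replication (rather than zero padding) avoids injecting spurious
    zero-motion samples at the sequence boundary, and preserves time-shift
    symmetry for constant inputs.
    """
    B, T, C = x.data.shape
    K, _, F = w.data.shape
    pad = K // 2
    xp = np.pad(x.data, ((0, 0), (pad, pad), (0, 0)), mode="edge")
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)  # (B,T,C,K)
    out_data = np.einsum("btck,kcf->btf", win, w.data, optimize=True) + b.data
    out = Tensor(out_data, (x, w, b))

    def bw(g):
        w._acc(np.einsum("btck,btf->kcf", win, g, optimize=True))
        b._acc(g.sum(axis=(0, 1)))
        gxp = np.zeros_like(xp)
        for k in range(K):
            gxp[:, k : k + T, :] += np.einsum("btf,cf->btc", g, w.data[k], optimize=True)
        gx = gxp[:, pad : pad + T, :].copy()
        gx[:, 0, :] += gxp[:, :pad, :].sum(axis=1)    # replicated edges fold back
        gx[:, -1, :] += gxp[:, pad + T :, :].sum(axis=1)
        x._acc(gx)

    out._backward = bw
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
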