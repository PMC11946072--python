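"""Minimal reverse-mode automatic differentiation on numpy arrays.

A `Tensor` wraps an ndarray and records the operation that produced it; a
call to `backward()` on a scalar loss topologically sorts the tape and
accumulates gradients.  Only the operations the restoration network needs are
implemented: broadcast arithmetic, (batched) matmul, 3x3 convolution via
im2col, 2x2 max pooling, nearest-neighbor up/down-sampling, channel
concatenation, reshape/transpose, ReLU/GELU/sigmoid, softmax and layer norm.
Gradients are checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling tape recording (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum grad down to `shape` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        req = _grad_enabled and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd ------------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, visited = [], set()

        def visit(t):
            if id(t) in visited or not t.requires_grad:
                return
            visited.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)
            t._parents = ()
            t._backward = None

    def _accum(self, g):
        g = np.ascontiguousarray(g)
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic ----------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, self.data.dtype))

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._result(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._result(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._result(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("tensor/tensor division not supported; multiply by reciprocal")
        return self * (1.0 / scalar)

    def __matmul__(self, other):
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.shape))

        return Tensor._result(a.data @ b.data, (a, b), backward)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        a = self
        orig = a.shape

        def backward(g):
            a._accum(g.reshape(orig))

        return Tensor._result(a.data.reshape(*shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)

        def backward(g):
            a._accum(g.transpose(inv))

        return Tensor._result(a.data.transpose(axes), (a,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def backward(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.shape).copy())

        return Tensor._result(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- nonlinearities ------------------------------------------------------
    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accum(g * mask)

        return Tensor._result(np.where(mask, a.data, 0), (a,), backward)

    def sigmoid(self):
        a = self
        y = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))

        def backward(g):
            a._accum(g * y * (1 - y))

        return Tensor._result(y, (a,), backward)

    def gelu(self):
        """tanh approximation of the Gaussian error linear unit."""
        a = self
        c = a.data.dtype.type(np.sqrt(2 / np.pi))
        x = a.data
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        y = 0.5 * x * (1 + t)

        def backward(g):
            dinner = c * (1 + 3 * 0.044715 * x**2)
            dy = 0.5 * (1 + t) + 0.5 * x * (1 - t**2) * dinner
            a._accum(g * dy)

        return Tensor._result(y, (a,), backward)

    def softmax(self, axis=-1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            s = (g * y).sum(axis=axis, keepdims=True)
            a._accum(y * (g - s))

        return Tensor._result(y, (a,), backward)

    # -- image ops (NCHW) ----------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor" = None, padding: int = 1):
        """2-D convolution, stride 1, square kernel, via im2col + matmul."""
        a, w = self, weight
        N, C, H, W = a.shape
        CO, CI, K, _ = w.shape
        if CI != C:
            raise ValueError("channel mismatch in conv2d")
        xp = np.pad(a.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        Ho, Wo = H + 2 * padding - K + 1, W + 2 * padding - K + 1
        # (N, C, K, K, Ho, Wo) view -> columns (N, Ho*Wo, C*K*K)
        win = np.lib.stride_tricks.sliding_window_view(xp, (K, K), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N, Ho * Wo, C * K * K)
        wmat = w.data.reshape(CO, C * K * K)
        out = cols @ wmat.T  # (N, Ho*Wo, CO)
        out = out.transpose(0, 2, 1).reshape(N, CO, Ho, Wo)
        if bias is not None:
            out = out + bias.data.reshape(1, CO, 1, 1)
        parents = (a, w) if bias is None else (a, w, bias)

        def backward(g):
            gflat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, CO)
            if w.requires_grad:
                gw = gflat.T @ cols.reshape(N * Ho * Wo, C * K * K)
                w._accum(gw.reshape(CO, C, K, K))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if a.requires_grad:
                gcols = (gflat @ wmat).reshape(N, Ho, Wo, C, K, K)
                # accumulate in NHWC, one transpose at the end
                gx = np.zeros((N, H + 2 * padding, W + 2 * padding, C), dtype=g.dtype)
                for ki in range(K):
                    for kj in range(K):
                        gx[:, ki : ki + Ho, kj : kj + Wo, :] += gcols[:, :, :, :, ki, kj]
                if padding:
                    gx = gx[:, padding:-padding, padding:-padding, :]
                a._accum(gx.transpose(0, 3, 1, 2))

        return Tensor._result(out, parents, backward)

    def maxpool2x2(self):
        a = self
        N, C, H, W = a.shape
        blocks = a.data.reshape(N, C, H // 2, 2, W // 2, 2)
        out = blocks.max(axis=(3, 5))
        mask = blocks == out[:, :, :, None, :, None]
        # split gradient among ties (ties are measure-zero for float activations)
        nties = mask.sum(axis=(3, 5), keepdims=True)

        def backward(g):
            gb = mask * (g[:, :, :, None, :, None] / nties)
            a._accum(gb.reshape(N, C, H, W))

        return Tensor._result(out, (a,), backward)

    def avgpool2x2(self):
        a = self
        N, C, H, W = a.shape
        out = a.data.reshape(N, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

        def backward(g):
            gb = np.broadcast_to(
                g[:, :, :, None, :, None] / 4.0, (N, C, H // 2, 2, W // 2, 2)
            )
            a._accum(gb.reshape(N, C, H, W))

        return Tensor._result(out, (a,), backward)

    def upsample2x2(self):
        """Nearest-neighbor 2x upsampling."""
        a = self
        N, C, H, W = a.shape
        out = a.data.repeat(2, axis=2).repeat(2, axis=3)

        def backward(g):
            a._accum(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

        return Tensor._result(out, (a,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._result(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)
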