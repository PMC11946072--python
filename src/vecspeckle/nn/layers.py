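"""Network building blocks on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = [
    "Module",
    "Parameter",
    "Conv2d",
    "Linear",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "TransformerBlock",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)
        self.requires_grad = True  # parameters stay trainable even under no_grad


class Module:
    """Base class with recursive parameter traversal and state (de)serialization."""

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}

        def walk(obj, key):
            if isinstance(obj, Parameter):
                out[key] = obj
            elif isinstance(obj, Module):
                for name, v in vars(obj).items():
                    walk(v, f"{key}.{name}" if key else name)
            elif isinstance(obj, (list, tuple)):
                for i, item in enumerate(obj):
                    walk(item, f"{key}.{i}")

        walk(self, prefix.rstrip("."))
        return out

    def parameters(self) -> list[Parameter]:
        return list(self.named_parameters().values())

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        if set(params) != set(state):
            raise ValueError("state dict does not match model parameters")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float32).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape).astype(np.float32) * np.sqrt(2.0 / fan_in)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        pad = (kernel - 1) // 2
        self.padding = pad
        self.weight = Parameter(_he(rng, (c_out, c_in, kernel, kernel), c_in * kernel * kernel))
        self.bias = Parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, padding=self.padding)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.weight = Parameter(_he(rng, (d_in, d_out), d_in))
        self.bias = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        norm = _ln_normalize(centered, var, self.eps)
        return norm * self.gamma + self.beta


def _ln_normalize(centered: Tensor, var: Tensor, eps: float) -> Tensor:
    """(x - mu) / sqrt(var + eps) with gradients through both arguments."""
    inv = _rsqrt(var + eps)
    return centered * inv


def _rsqrt(t: Tensor) -> Tensor:
    y = t.data**-0.5

    def backward(g):
        if t.requires_grad:
            t._accum(g * (-0.5) * t.data**-1.5)

    return Tensor._result(y, (t,), backward)


class MultiHeadSelfAttention(Module):
    """Standard scaled dot-product self-attention over a token sequence."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        N, T, D = x.shape
        h, dh = self.n_heads, self.d_head
        qkv = self.qkv(x)  # (N, T, 3D)
        qkv = qkv.reshape(N, T, 3, h, dh).transpose(2, 0, 3, 1, 4)  # (3, N, h, T, dh)
        q = qkv.reshape(3, N * h, T, dh)
        # split via explicit slicing tensors
        q_, k_, v_ = _split3(q)
        att = (q_ @ _swap(k_)) * (1.0 / np.sqrt(dh))
        att = att.softmax(axis=-1)
        out = att @ v_  # (N*h, T, dh)
        out = out.reshape(N, h, T, dh).transpose(0, 2, 1, 3).reshape(N, T, D)
        return self.proj(out)


def _swap(t: Tensor) -> Tensor:
    axes = tuple(range(t.ndim - 2)) + (t.ndim - 1, t.ndim - 2)
    return t.transpose(*axes)


def _split3(t: Tensor) -> tuple[Tensor, Tensor, Tensor]:
    """Split the leading axis of a (3, ...) tensor into three tensors."""
    outs = []
    for i in range(3):
        def backward(g, i=i):
            if t.requires_grad:
                full = np.zeros_like(t.data)
                full[i] = g
                t._accum(full)

        outs.append(Tensor._result(t.data[i], (t,), backward))
    return tuple(outs)


class TransformerBlock(Module):
    """Pre-norm self-attention block with a GELU feed-forward sublayer."""

    def __init__(self, dim: int, n_heads: int, ff_mult: int, rng: np.random.Generator):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.ln2 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_mult * dim, rng)
        self.ff2 = Linear(ff_mult * dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.ff2(self.ff1(self.ln2(x)).gelu())
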