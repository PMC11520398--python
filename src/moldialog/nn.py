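"""Minimal reverse-mode autodiff and transformer building blocks on numpy.

Just enough machinery for the toy twin seq2seq: broadcast-aware
elementwise ops, batched matmul, softmax, embedding lookup, a fused
masked cross-entropy, layer normalization, multi-head attention, and Adam.
Everything is deterministic given the numpy Generator used for
initialization, so training trajectories are bit-reproducible.

Gradient correctness is checked against central finite differences in the
test suite.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _op(data, parents, backward):
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req, parents=parents if req else (),
                      backward=backward if req else None)

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(grad):
            return (_unbroadcast(grad, self.shape), _unbroadcast(grad, other.shape))

        return Tensor._op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward(grad):
            return (
                _unbroadcast(grad * other.data, self.shape),
                _unbroadcast(grad * self.data, other.shape),
            )

        return Tensor._op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(grad):
            return (grad * exponent * self.data ** (exponent - 1),)

        return Tensor._op(out_data, (self,), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        out_data = self.data @ other.data

        def backward(grad):
            ga = grad @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ grad
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return Tensor._op(out_data, (self, other), backward)

    __matmul__ = matmul

    def transpose(self, *axes):
        out_data = self.data.transpose(axes)
        inverse = np.argsort(axes)

        def backward(grad):
            return (grad.transpose(inverse),)

        return Tensor._op(out_data, (self,), backward)

    def reshape(self, *shape):
        out_data = self.data.reshape(shape)
        orig = self.shape

        def backward(grad):
            return (grad.reshape(orig),)

        return Tensor._op(out_data, (self,), backward)

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(grad):
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).copy(),)

        return Tensor._op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(grad):
            return (grad * out_data,)

        return Tensor._op(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(grad):
            return (grad / self.data,)

        return Tensor._op(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(grad):
            return (grad * (1.0 - out_data ** 2),)

        return Tensor._op(out_data, (self,), backward)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward(grad):
            return (grad * (self.data > 0),)

        return Tensor._op(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(grad):
            dot = (grad * out_data).sum(axis=axis, keepdims=True)
            return (out_data * (grad - dot),)

        return Tensor._op(out_data, (self,), backward)

    # -- backprop -----------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() needs a scalar loss")
        order: List[Tensor] = []
        seen = set()

        def topo(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                topo(p)
            order.append(t)

        topo(self)
        for t in order:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is None:
                continue
            grads = t._backward(t.grad)
            for parent, g in zip(t._parents, grads):
                if parent.requires_grad and g is not None:
                    if parent.grad is None:
                        parent.grad = np.zeros_like(parent.data)
                    parent.grad += g


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup into an embedding table, differentiable w.r.t. the table."""
    out_data = weight.data[ids]

    def backward(grad):
        g = np.zeros_like(weight.data)
        np.add.at(g, ids, grad)
        return (g,)

    return Tensor._op(out_data, (weight,), backward)


def cross_entropy(logits: Tensor, targets: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean masked token cross-entropy.

    logits: (..., V); targets: integer ids (...,); mask: 0/1 (...,).
    """
    shifted = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(shifted).sum(axis=-1)) + logits.data.max(axis=-1)
    picked = np.take_along_axis(
        logits.data, targets[..., None], axis=-1
    ).squeeze(-1)
    n = max(mask.sum(), 1)
    loss_val = (((logsumexp - picked) * mask).sum() / n)

    def backward(grad):
        probs = np.exp(shifted)
        probs /= probs.sum(axis=-1, keepdims=True)
        one_hot = np.zeros_like(probs)
        np.put_along_axis(one_hot, targets[..., None], 1.0, axis=-1)
        g = (probs - one_hot) * mask[..., None] / n
        return (grad * g,)

    return Tensor._op(np.array(loss_val), (logits,), backward)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Module:
    """Base class: recursively collects named parameters."""

    def parameters(self, prefix: str = "") -> Dict[str, Tensor]:
        params: Dict[str, Tensor] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                params[key] = value
            elif isinstance(value, Module):
                params.update(value.parameters(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        params.update(item.parameters(f"{key}.{i}."))
        return params


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / (n_in + n_out))
        self.w = Tensor(rng.normal(0.0, scale, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class MultiHeadAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError("hidden size must divide by heads")
        self.heads = heads
        self.dim = dim
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def __call__(self, q: Tensor, kv: Tensor, mask: np.ndarray) -> Tensor:
        """mask: additive, broadcastable to (B, heads, Tq, Tk)."""
        B, Tq, D = q.shape
        Tk = kv.shape[1]
        H, dh = self.heads, D // self.heads

        def split(t: Tensor, T: int) -> Tensor:
            return t.reshape(B, T, H, dh).transpose(0, 2, 1, 3)

        qh = split(self.wq(q), Tq)
        kh = split(self.wk(kv), Tk)
        vh = split(self.wv(kv), Tk)
        scores = qh @ kh.transpose(0, 1, 3, 2) * (1.0 / math.sqrt(dh)) + Tensor(mask)
        attn = scores.softmax(axis=-1)
        out = (attn @ vh).transpose(0, 2, 1, 3).reshape(B, Tq, D)
        return self.wo(out)


class FeedForward(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.w1 = Linear(dim, hidden, rng)
        self.w2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.w2(self.w1(x).relu())


class EncoderLayer(Module):
    def __init__(self, dim: int, heads: int, ffn: int, rng):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, heads, rng)
        self.ln2 = LayerNorm(dim)
        self.ff = FeedForward(dim, ffn, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        h = self.ln1(x)
        x = x + self.attn(h, h, mask)
        return x + self.ff(self.ln2(x))


class DecoderLayer(Module):
    def __init__(self, dim: int, heads: int, ffn: int, rng):
        self.ln1 = LayerNorm(dim)
        self.self_attn = MultiHeadAttention(dim, heads, rng)
        self.ln2 = LayerNorm(dim)
        self.cross_attn = MultiHeadAttention(dim, heads, rng)
        self.ln3 = LayerNorm(dim)
        self.ff = FeedForward(dim, ffn, rng)

    def __call__(self, x, memory, self_mask, cross_mask):
        h = self.ln1(x)
        x = x + self.self_attn(h, h, self_mask)
        x = x + self.cross_attn(self.ln2(x), memory, cross_mask)
        return x + self.ff(self.ln3(x))


NEG_INF = -1e9


def padding_mask(lengths: Sequence[int], T: int) -> np.ndarray:
    """(B, 1, 1, T) additive mask hiding padded key positions."""
    B = len(lengths)
    mask = np.zeros((B, 1, 1, T))
    for b, n in enumerate(lengths):
        mask[b, :, :, n:] = NEG_INF
    return mask


def causal_mask(T: int) -> np.ndarray:
    """(1, 1, T, T) additive mask hiding future positions."""
    return np.triu(np.full((1, 1, T, T), NEG_INF), k=1)


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, params: Dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1 ** self.t)
            v_hat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def state(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v}

    def load_state(self, state: dict) -> None:
        self.t = state["t"]
        self.m = {k: np.array(v) for k, v in state["m"].items()}
        self.v = {k: np.array(v) for k, v in state["v"].items()}
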