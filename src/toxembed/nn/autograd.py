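"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough machinery for a small bidirectional transformer encoder and
MLP heads: broadcast-aware elementwise arithmetic, (batched) matmul,
activations, softmax, layer normalization, embedding lookup, dropout,
reductions and a fused masked cross-entropy.  Graphs are built eagerly
and freed after ``backward``; the float dtype is configurable (module
default float32).
"""

from __future__ import annotations

import numpy as np

Array = np.ndarray

#: floating dtype of all graph tensors.  float32 is the training default
#: (twice the throughput on a CPU); switch to float64 for high-precision
#: checks such as finite-difference gradient verification.
DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    global DTYPE
    if dtype not in (np.float32, np.float64):
        raise ValueError("dtype must be np.float32 or np.float64")
    DTYPE = dtype


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "_parents", "_grad_fn", "requires_grad")

    def __init__(self, data, parents=(), grad_fn=None, requires_grad=False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: Array | None = None
        self._parents: tuple[Tensor, ...] = parents
        self._grad_fn = grad_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    # -- graph traversal ----------------------------------------------------

    def backward(self, grad: Array | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._grad_fn is not None and node.grad is not None:
                node._grad_fn(node.grad)
            if node is not self:
                node._grad_fn = None  # free closures as we go

    def _accum(self, grad: Array) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- operator sugar -----------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data, (a, b))

    def grad_fn(g):
        a._accum(_unbroadcast(g, a.data.shape))
        b._accum(_unbroadcast(g, b.data.shape))

    out._grad_fn = grad_fn
    return out


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data * b.data, (a, b))

    def grad_fn(g):
        a._accum(_unbroadcast(g * b.data, a.data.shape))
        b._accum(_unbroadcast(g * a.data, b.data.shape))

    out._grad_fn = grad_fn
    return out


def power(a, exponent: float) -> Tensor:
    """Elementwise a**exponent for a scalar exponent."""
    a = as_tensor(a)
    out = Tensor(a.data ** exponent, (a,))

    def grad_fn(g):
        with np.errstate(divide="ignore", invalid="ignore"):
            local = exponent * a.data ** (exponent - 1.0)
        local = np.nan_to_num(local, nan=0.0, posinf=0.0, neginf=0.0)
        a._accum(g * local)

    out._grad_fn = grad_fn
    return out


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(np.matmul(a.data, b.data), (a, b))

    def grad_fn(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        a._accum(_unbroadcast(ga, a.data.shape))
        b._accum(_unbroadcast(gb, b.data.shape))

    out._grad_fn = grad_fn
    return out


def relu(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.maximum(a.data, 0.0), (a,))

    def grad_fn(g):
        a._accum(g * (a.data > 0))

    out._grad_fn = grad_fn
    return out


def tanh(a) -> Tensor:
    a = as_tensor(a)
    t = np.tanh(a.data)
    out = Tensor(t, (a,))

    def grad_fn(g):
        a._accum(g * (1.0 - t * t))

    out._grad_fn = grad_fn
    return out


_GELU_C = np.sqrt(2.0 / np.pi)


def gelu(a) -> Tensor:
    """Gaussian error linear unit (tanh approximation)."""
    a = as_tensor(a)
    x = a.data
    inner = _GELU_C * (x + 0.044715 * x**3)
    t = np.tanh(inner)
    out = Tensor(0.5 * x * (1.0 + t), (a,))

    def grad_fn(g):
        dinner = _GELU_C * (1.0 + 3 * 0.044715 * x**2)
        local = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * dinner
        a._accum(g * local)

    out._grad_fn = grad_fn
    return out


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    s = np.empty_like(a.data)
    pos = a.data >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    e = np.exp(a.data[~pos])
    s[~pos] = e / (1.0 + e)
    out = Tensor(s, (a,))

    def grad_fn(g):
        a._accum(g * s * (1.0 - s))

    out._grad_fn = grad_fn
    return out


def log_sigmoid(a) -> Tensor:
    """Numerically stable log(sigmoid(a)); gradient is sigmoid(-a)."""
    a = as_tensor(a)
    x = a.data
    val = np.where(x >= 0, -np.log1p(np.exp(-np.abs(x))), x - np.log1p(np.exp(-np.abs(x))))
    out = Tensor(val, (a,))

    def grad_fn(g):
        sneg = np.empty_like(x)
        pos = x >= 0
        sneg[pos] = np.exp(-x[pos]) / (1.0 + np.exp(-x[pos]))
        sneg[~pos] = 1.0 / (1.0 + np.exp(x[~pos]))
        a._accum(g * sneg)

    out._grad_fn = grad_fn
    return out


def softmax(a, mask: Array | None = None) -> Tensor:
    """Softmax over the last axis; ``mask`` (broadcastable, 1 = keep)
    excludes positions by additive -inf before normalization."""
    a = as_tensor(a)
    z = a.data
    if mask is not None:
        z = np.where(mask.astype(bool), z, -1e30)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(s, (a,))

    def grad_fn(g):
        dot = (g * s).sum(axis=-1, keepdims=True)
        a._accum(s * (g - dot))

    out._grad_fn = grad_fn
    return out


def layer_norm(a, gain, bias, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    a, gain, bias = as_tensor(a), as_tensor(gain), as_tensor(bias)
    mu = a.data.mean(axis=-1, keepdims=True)
    xc = a.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gain.data + bias.data, (a, gain, bias))

    def grad_fn(g):
        gain._accum(_unbroadcast(g * xhat, gain.data.shape))
        bias._accum(_unbroadcast(g, bias.data.shape))
        gx = g * gain.data
        term = gx - gx.mean(axis=-1, keepdims=True) - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
        a._accum(term * inv)

    out._grad_fn = grad_fn
    return out


def embedding(table, idx: Array) -> Tensor:
    """Row lookup ``table[idx]`` with scatter-add gradient."""
    table = as_tensor(table)
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(table.data[idx], (table,))

    def grad_fn(g):
        if table.requires_grad:
            acc = np.zeros_like(table.data)
            np.add.at(acc, idx.reshape(-1), g.reshape(-1, g.shape[-1]))
            table._accum(acc)

    out._grad_fn = grad_fn
    return out


def dropout(a, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    a = as_tensor(a)
    if not training or rate <= 0.0:
        return a
    keep = rng.random(a.data.shape) >= rate
    scale = 1.0 / (1.0 - rate)
    out = Tensor(a.data * keep * scale, (a,))

    def grad_fn(g):
        a._accum(g * keep * scale)

    out._grad_fn = grad_fn
    return out


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.reshape(shape), (a,))

    def grad_fn(g):
        a._accum(g.reshape(a.data.shape))

    out._grad_fn = grad_fn
    return out


def swapaxes(a, ax1: int, ax2: int) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.swapaxes(a.data, ax1, ax2), (a,))

    def grad_fn(g):
        a._accum(np.swapaxes(g, ax1, ax2))

    out._grad_fn = grad_fn
    return out


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def grad_fn(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._grad_fn = grad_fn
    return out


def take_position(a, position: int) -> Tensor:
    """Select one sequence position: (B, T, H) -> (B, H)."""
    a = as_tensor(a)
    out = Tensor(a.data[:, position, :], (a,))

    def grad_fn(g):
        acc = np.zeros_like(a.data)
        acc[:, position, :] = g
        a._accum(acc)

    out._grad_fn = grad_fn
    return out


def mean_over_mask(a, mask: Array) -> Tensor:
    """Mean of (B, T, H) over axis 1 restricted to mask (B, T)."""
    a = as_tensor(a)
    m = mask.astype(np.float64)
    denom = m.sum(axis=1, keepdims=True)
    denom = np.maximum(denom, 1.0)
    out = Tensor((a.data * m[..., None]).sum(axis=1) / denom, (a,))

    def grad_fn(g):
        a._accum(g[:, None, :] * (m / denom)[..., None])

    out._grad_fn = grad_fn
    return out


def sum_all(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.sum(), (a,))

    def grad_fn(g):
        a._accum(np.broadcast_to(g, a.data.shape).copy())

    out._grad_fn = grad_fn
    return out


def mean_all(a) -> Tensor:
    a = as_tensor(a)
    n = a.data.size
    out = Tensor(a.data.mean(), (a,))

    def grad_fn(g):
        a._accum(np.broadcast_to(g / n, a.data.shape).copy())

    out._grad_fn = grad_fn
    return out


def masked_cross_entropy(logits, targets: Array, mask: Array) -> Tensor:
    """Fused mean softmax cross-entropy over masked positions.

    ``logits``: (B, T, V); ``targets``: (B, T) int; ``mask``: (B, T) bool.
    Gradient flows only through masked positions.
    """
    logits = as_tensor(logits)
    t = np.asarray(targets, dtype=np.int64)
    m = np.asarray(mask, dtype=bool)
    n_masked = int(m.sum())
    if n_masked == 0:
        raise ValueError("no masked positions")
    z = logits.data
    zmax = z.max(axis=-1, keepdims=True)
    e = np.exp(z - zmax)
    denom = e.sum(axis=-1, keepdims=True)
    logp = (z - zmax) - np.log(denom)
    nll = -np.take_along_axis(logp, t[..., None], axis=-1)[..., 0]
    out = Tensor(nll[m].sum() / n_masked, (logits,))
    probs = e / denom

    def grad_fn(g):
        grad = probs.copy()
        np.put_along_axis(
            grad, t[..., None],
            np.take_along_axis(grad, t[..., None], axis=-1) - 1.0, axis=-1,
        )
        grad *= (m[..., None] / n_masked) * g
        logits._accum(grad)

    out._grad_fn = grad_fn
    return out
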