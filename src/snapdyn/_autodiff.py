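"""Minimal reverse-mode automatic differentiation on numpy arrays.

The training objective backpropagates through an unrolled Euler–Maruyama
solve of an interacting SDE (whose drift contains masked multi-head
self-attention) and through unrolled log-domain Sinkhorn iterations.  Only
the primitives those computations need are implemented, each with a fused
backward pass so the graph stays small (a few dozen nodes per solver step).

Everything is float64.  Gradients are plain ``np.ndarray``s accumulated on
leaf :class:`Tensor`s; there is no grad-mode switching — a forward pass that
is never ``backward()``-ed is just a forward pass.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "constant", "add", "sub", "mul", "scale", "matmul", "linear",
    "leaky_relu", "exp", "log", "sqrt", "sum_", "mean_", "sumsq", "concat",
    "transpose", "logsumexp", "masked_softmax", "layer_norm",
    "pairwise_sqdist", "relu",
]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    # -- conveniences -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape})"

    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    # -- reverse pass -------------------------------------------------
    def backward(self, grad=None):
        """Accumulate gradients of ``self`` w.r.t. every ancestor leaf."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: unrolled solvers produce deep graphs
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None


def constant(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray) -> None:
    # grads are only ever rebound, never mutated in place, so sharing is safe
    if t.grad is None:
        t.grad = g
    else:
        t.grad = t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (reverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = constant(a), constant(b)
    out_data = a.data + b.data

    def _bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return Tensor(out_data, (a, b), _bw)


def sub(a, b) -> Tensor:
    a, b = constant(a), constant(b)
    out_data = a.data - b.data

    def _bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))

    return Tensor(out_data, (a, b), _bw)


def mul(a, b) -> Tensor:
    a, b = constant(a), constant(b)
    out_data = a.data * b.data

    def _bw(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, (a, b), _bw)


def scale(a, c: float) -> Tensor:
    """Multiply by a python scalar constant (no gradient for ``c``)."""
    a = constant(a)
    c = float(c)

    def _bw(g):
        _accum(a, g * c)

    return Tensor(a.data * c, (a,), _bw)


def matmul(a, b) -> Tensor:
    a, b = constant(a), constant(b)
    out_data = a.data @ b.data

    def _bw(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    return Tensor(out_data, (a, b), _bw)


def linear(x, W, b) -> Tensor:
    """Affine map ``x @ W + b`` with a fused backward."""
    x, W, b = constant(x), constant(W), constant(b)
    out_data = x.data @ W.data + b.data

    def _bw(g):
        _accum(x, g @ W.data.T)
        _accum(W, x.data.T @ g)
        _accum(b, g.sum(axis=0))

    return Tensor(out_data, (x, W, b), _bw)


def transpose(a) -> Tensor:
    a = constant(a)

    def _bw(g):
        _accum(a, g.T)

    return Tensor(a.data.T, (a,), _bw)


# ---------------------------------------------------------------------
# nonlinearities / reductions
# ---------------------------------------------------------------------

def leaky_relu(x, slope: float = 0.01) -> Tensor:
    x = constant(x)
    pos = x.data > 0
    out_data = np.where(pos, x.data, slope * x.data)

    def _bw(g):
        _accum(x, np.where(pos, g, slope * g))

    return Tensor(out_data, (x,), _bw)


def relu(x) -> Tensor:
    return leaky_relu(x, 0.0)


def exp(x) -> Tensor:
    x = constant(x)
    out_data = np.exp(x.data)

    def _bw(g):
        _accum(x, g * out_data)

    return Tensor(out_data, (x,), _bw)


def log(x) -> Tensor:
    x = constant(x)

    def _bw(g):
        _accum(x, g / x.data)

    return Tensor(np.log(x.data), (x,), _bw)


def sqrt(x) -> Tensor:
    x = constant(x)
    out_data = np.sqrt(x.data)

    def _bw(g):
        _accum(x, g * 0.5 / out_data)

    return Tensor(out_data, (x,), _bw)


def sum_(x, axis=None, keepdims=False) -> Tensor:
    x = constant(x)
    out_data = x.data.sum(axis=axis, keepdims=keepdims)

    def _bw(g):
        gg = np.asarray(g)
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        _accum(x, np.broadcast_to(gg, x.data.shape).copy())

    return Tensor(out_data, (x,), _bw)


def mean_(x, axis=None, keepdims=False) -> Tensor:
    x = constant(x)
    n = x.data.size if axis is None else x.data.shape[axis]
    return scale(sum_(x, axis=axis, keepdims=keepdims), 1.0 / n)


def sumsq(x) -> Tensor:
    """Scalar sum of squares (drift action integrand)."""
    x = constant(x)
    out_data = np.array(np.sum(x.data * x.data))

    def _bw(g):
        _accum(x, (2.0 * float(g)) * x.data)

    return Tensor(out_data, (x,), _bw)


def concat(tensors, axis: int) -> Tensor:
    tensors = [constant(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return Tensor(out_data, tuple(tensors), _bw)


def logsumexp(x, axis: int, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp along ``axis`` (Sinkhorn workhorse)."""
    x = constant(x)
    m = np.max(x.data, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    e = np.exp(x.data - m)
    s = e.sum(axis=axis, keepdims=True)
    out = m + np.log(s)
    w = e / s  # softmax weights, reused in backward
    out_data = out if keepdims else np.squeeze(out, axis=axis)

    def _bw(g):
        gg = np.asarray(g)
        if not keepdims:
            gg = np.expand_dims(gg, axis)
        _accum(x, gg * w)

    return Tensor(out_data, (x,), _bw)


def masked_softmax(logits, mask: np.ndarray) -> Tensor:
    """Row softmax of ``logits`` restricted to entries where ``mask`` is 1.

    Equivalent to setting masked logits to -inf before the softmax, but
    implemented by zeroing the exponentials so no non-finite values appear.
    Rows whose mask is entirely zero yield an all-zero row.
    """
    logits = constant(logits)
    mask = np.asarray(mask, dtype=np.float64)
    m = np.max(np.where(mask > 0, logits.data, -np.inf), axis=-1, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    e = np.exp(logits.data - m) * mask
    s = e.sum(axis=-1, keepdims=True)
    safe = np.where(s > 0, s, 1.0)
    p = e / safe

    def _bw(g):
        inner = (g * p).sum(axis=-1, keepdims=True)
        _accum(logits, p * (g - inner))

    return Tensor(p, (logits,), _bw)


def layer_norm(x, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with learnable gain/offset."""
    x, gamma, beta = constant(x), constant(gamma), constant(beta)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = gamma.data * xhat + beta.data

    def _bw(g):
        _accum(gamma, _unbroadcast(g * xhat, gamma.data.shape))
        _accum(beta, _unbroadcast(g, beta.data.shape))
        gx = g * gamma.data
        d = x.data.shape[-1]
        gx_mean = gx.mean(axis=-1, keepdims=True)
        gxxhat_mean = (gx * xhat).mean(axis=-1, keepdims=True)
        _accum(x, inv * (gx - gx_mean - xhat * gxxhat_mean))

    return Tensor(out_data, (x, gamma, beta), _bw)


def pairwise_sqdist(x, y) -> Tensor:
    """Squared euclidean cost matrix C[i, j] = ||x_i - y_j||^2."""
    x, y = constant(x), constant(y)
    xx = (x.data * x.data).sum(axis=1)
    yy = (y.data * y.data).sum(axis=1)
    out_data = xx[:, None] + yy[None, :] - 2.0 * (x.data @ y.data.T)
    np.maximum(out_data, 0.0, out=out_data)

    def _bw(g):
        _accum(x, 2.0 * (g.sum(axis=1)[:, None] * x.data - g @ y.data))
        _accum(y, 2.0 * (g.sum(axis=0)[:, None] * y.data - g.T @ x.data))

    return Tensor(out_data, (x, y), _bw)
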