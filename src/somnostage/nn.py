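"""Compact NumPy neural-network core: reverse-mode autodiff, LSTM layers,
batch normalisation, temporal attention, dropout and the AdamW optimizer.

The engine is a small dynamic tape over 2-D NumPy arrays: every ``Tensor``
records its parents and a backward closure, and ``backward()`` walks the
graph in reverse topological order.  Sequences are handled as Python
lists of (batch × features) tensors, one per timestep, which keeps every
primitive a plain matrix operation.  The op set is exactly what the
attention-LSTM classifier needs; each op's gradient is validated against
central finite differences in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Tensor",
    "add", "sub", "mul", "div", "matmul", "tanh", "sigmoid", "relu",
    "square", "sqrt_t", "mean0", "sum_all", "scale", "cols", "vconcat",
    "hconcat", "softmax_rows", "weighted_softmax_xent",
    "LstmLayer", "BatchNorm", "Dense", "TemporalAttention", "dropout_mask",
    "AdamW",
]


class Tensor:
    """A node in the computation graph holding a float64 array."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=True):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        """Reverse-mode sweep from this (scalar) tensor."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _binary(a: Tensor, b: Tensor, out_data, da, db) -> Tensor:
    out = Tensor(out_data, parents=(a, b))

    def backward():
        if a.requires_grad:
            a._accumulate(_unbroadcast(da(out.grad), a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(db(out.grad), b.data.shape))

    out._backward = backward
    return out


def add(a, b):
    return _binary(a, b, a.data + b.data, lambda g: g, lambda g: g)


def sub(a, b):
    return _binary(a, b, a.data - b.data, lambda g: g, lambda g: -g)


def mul(a, b):
    return _binary(a, b, a.data * b.data,
                   lambda g: g * b.data, lambda g: g * a.data)


def div(a, b):
    return _binary(a, b, a.data / b.data,
                   lambda g: g / b.data,
                   lambda g: -g * a.data / (b.data ** 2))


def matmul(a, b):
    out = Tensor(a.data @ b.data, parents=(a, b))

    def backward():
        if a.requires_grad:
            a._accumulate(out.grad @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ out.grad)

    out._backward = backward
    return out


def _unary(a: Tensor, out_data, da) -> Tensor:
    out = Tensor(out_data, parents=(a,))

    def backward():
        if a.requires_grad:
            a._accumulate(da(out.grad))

    out._backward = backward
    return out


def tanh(a):
    y = np.tanh(a.data)
    return _unary(a, y, lambda g, y=y: g * (1.0 - y ** 2))


def sigmoid(a):
    y = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))
    return _unary(a, y, lambda g, y=y: g * y * (1.0 - y))


def relu(a):
    m = a.data > 0
    return _unary(a, a.data * m, lambda g, m=m: g * m)


def square(a):
    return _unary(a, a.data ** 2, lambda g: g * 2.0 * a.data)


def sqrt_t(a):
    y = np.sqrt(a.data)
    return _unary(a, y, lambda g, y=y: g * 0.5 / y)


def scale(a, k: float):
    return _unary(a, a.data * k, lambda g: g * k)


def mean0(a):
    """Column means -> shape (1, F)."""
    n = a.data.shape[0]
    return _unary(a, a.data.mean(axis=0, keepdims=True),
                  lambda g: np.broadcast_to(g / n, a.data.shape).copy())


def sum_all(a):
    return _unary(a, a.data.sum(), lambda g: np.full_like(a.data, float(g)))


def cols(a, j0: int, j1: int):
    """Column slice [:, j0:j1]."""
    out = Tensor(a.data[:, j0:j1], parents=(a,))

    def backward():
        if a.requires_grad:
            g = np.zeros_like(a.data)
            g[:, j0:j1] = out.grad
            a._accumulate(g)

    out._backward = backward
    return out


def vconcat(tensors):
    """Stack row-wise; backward splits the gradient back."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=0),
                 parents=tuple(tensors))

    def backward():
        ofs = 0
        for t in tensors:
            n = t.data.shape[0]
            if t.requires_grad:
                t._accumulate(out.grad[ofs:ofs + n])
            ofs += n

    out._backward = backward
    return out


def hconcat(tensors):
    """Stack column-wise; backward splits the gradient back."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=1),
                 parents=tuple(tensors))

    def backward():
        ofs = 0
        for t in tensors:
            n = t.data.shape[1]
            if t.requires_grad:
                t._accumulate(out.grad[:, ofs:ofs + n])
            ofs += n

    out._backward = backward
    return out


def softmax_rows(a):
    """Row-wise softmax (stable)."""
    z = a.data - a.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=1, keepdims=True)

    def da(g, y=y):
        return (g - (g * y).sum(axis=1, keepdims=True)) * y

    return _unary(a, y, da)


def weighted_softmax_xent(logits: Tensor, y_onehot: np.ndarray,
                          sample_w: np.ndarray) -> Tensor:
    """Mean weighted categorical cross-entropy over the batch (fused op)."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = logits.data.shape[0]
    ce = -(y_onehot * np.log(np.maximum(p, 1e-12))).sum(axis=1)
    loss = float((sample_w * ce).mean())
    out = Tensor(loss, parents=(logits,))

    def backward():
        if logits.requires_grad:
            g = (p - y_onehot) * sample_w[:, None] / n
            logits._accumulate(out.grad * g)

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    limit = math.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


class LstmLayer:
    """Standard LSTM over a list of per-timestep (B × F) tensors.

    Gate order i, f, g, o; forget-gate bias initialised to 1.  Kernels
    Glorot-uniform, recurrent kernels orthogonal.
    """

    def __init__(self, n_in: int, units: int, rng: np.random.Generator):
        self.units = units
        self.W = Tensor(_glorot(rng, (n_in, 4 * units)))
        u = np.concatenate(
            [_orthogonal(rng, units) for _ in range(4)], axis=1
        )
        self.U = Tensor(u)
        b = np.zeros((1, 4 * units))
        b[0, units:2 * units] = 1.0
        self.b = Tensor(b)

    @property
    def params(self):
        return [self.W, self.U, self.b]

    @property
    def kernels(self):
        """Weight matrices subject to L2 regularisation."""
        return [self.W, self.U]

    def forward(self, xs: list) -> list:
        """Return the full hidden sequence [h_1 … h_T]."""
        B = xs[0].data.shape[0]
        H = self.units
        h = Tensor(np.zeros((B, H)), requires_grad=False)
        c = Tensor(np.zeros((B, H)), requires_grad=False)
        out = []
        for x in xs:
            zx = matmul(x, self.W)
            zh = matmul(h, self.U)
            z = add(add(zx, zh), self.b)
            i = sigmoid(cols(z, 0, H))
            f = sigmoid(cols(z, H, 2 * H))
            g = tanh(cols(z, 2 * H, 3 * H))
            o = sigmoid(cols(z, 3 * H, 4 * H))
            c = add(mul(f, c), mul(i, g))
            h = mul(o, tanh(c))
            out.append(h)
        return out


class BatchNorm:
    """Feature-wise batch normalisation with running statistics."""

    def __init__(self, n_features: int, momentum: float = 0.9,
                 eps: float = 1e-3):
        self.gamma = Tensor(np.ones((1, n_features)))
        self.beta = Tensor(np.zeros((1, n_features)))
        self.running_mean = np.zeros((1, n_features))
        self.running_var = np.ones((1, n_features))
        self.momentum = momentum
        self.eps = eps

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: Tensor, train: bool) -> Tensor:
        if train:
            mu = mean0(x)
            var = mean0(square(sub(x, mu)))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu.data)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var.data)
            denom = sqrt_t(add(var, Tensor(np.full_like(var.data, self.eps),
                                           requires_grad=False)))
            xn = div(sub(x, mu), denom)
        else:
            xn = Tensor((x.data - self.running_mean)
                        / np.sqrt(self.running_var + self.eps), parents=(x,))

            def backward():
                if x.requires_grad:
                    x._accumulate(xn.grad / np.sqrt(self.running_var + self.eps))

            xn._backward = backward
        return add(mul(xn, self.gamma), self.beta)

    def forward_seq(self, xs: list, train: bool) -> list:
        """Normalise a hidden sequence using statistics pooled over batch × time."""
        T = len(xs)
        flat = vconcat(xs)
        y = self.forward(flat, train)
        B = xs[0].data.shape[0]
        return [_rows(y, t * B, (t + 1) * B) for t in range(T)]


def _rows(a: Tensor, i0: int, i1: int) -> Tensor:
    out = Tensor(a.data[i0:i1], parents=(a,))

    def backward():
        if a.requires_grad:
            g = np.zeros_like(a.data)
            g[i0:i1] = out.grad
            a._accumulate(g)

    out._backward = backward
    return out


class Dense:
    """Affine layer y = xW + b."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Tensor(_glorot(rng, (n_in, n_out)))
        self.b = Tensor(np.zeros((1, n_out)))

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.W), self.b)


class TemporalAttention:
    """Additive temporal attention over a hidden sequence.

    Scores s_t = v·tanh(W h_t + b) are softmax-normalised over time and
    each hidden vector is rescaled by its weight: out_t = a_t · h_t.
    The attended output keeps the sequence shape.
    """

    def __init__(self, n_hidden: int, rng: np.random.Generator):
        self.W = Tensor(_glorot(rng, (n_hidden, n_hidden)))
        self.b = Tensor(np.zeros((1, n_hidden)))
        self.v = Tensor(_glorot(rng, (n_hidden, 1)))

    @property
    def params(self):
        return [self.W, self.b, self.v]

    def forward(self, hs: list):
        scores = [matmul(tanh(add(matmul(h, self.W), self.b)), self.v)
                  for h in hs]                      # each (B, 1)
        a = softmax_rows(hconcat(scores))           # (B, T)
        out = [mul(h, cols(a, t, t + 1)) for t, h in enumerate(hs)]
        return out, a


def dropout_mask(x: Tensor, rate: float, rng: np.random.Generator,
                 train: bool) -> Tensor:
    """Inverted dropout: identity at inference."""
    if not train or rate <= 0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return mul(x, Tensor(mask, requires_grad=False))


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

@dataclass
class AdamW:
    """AdamW: Adam moments plus decoupled weight decay."""

    params: list
    lr: float = 5e-4
    weight_decay: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    _m: list = field(default_factory=list)
    _v: list = field(default_factory=list)

    def __post_init__(self):
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g ** 2
            p.data -= self.lr * (
                (m / b1t) / (np.sqrt(v / b2t) + self.eps)
                + self.weight_decay * p.data
            )

    def zero_grad(self):
        for p in self.params:
            p.grad = None
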