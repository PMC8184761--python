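"""Minimal reverse-mode automatic differentiation and recurrent layers.

A small tape-based autodiff engine on numpy arrays, sufficient for the
fragment-intensity network: GRU cells (uni- and bidirectional), additive
attention, dense layers, dropout, the masked spectral-angle loss and an Adam
optimizer.  Everything is float64 and CPU-only by design; the networks this
package trains are desk-scale.
"""

from __future__ import annotations

import math

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)


def _wrap(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data + b.data, (a, b))

    def backward(grad):
        a._accumulate(_unbroadcast(grad, a.data.shape))
        b._accumulate(_unbroadcast(grad, b.data.shape))

    out._backward = backward
    return out


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data * b.data, (a, b))

    def backward(grad):
        a._accumulate(_unbroadcast(grad * b.data, a.data.shape))
        b._accumulate(_unbroadcast(grad * a.data, b.data.shape))

    out._backward = backward
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, (a, b))

    def backward(grad):
        a._accumulate(grad @ b.data.T)
        b._accumulate(a.data.T @ grad)

    out._backward = backward
    return out


def tanh(a: Tensor) -> Tensor:
    value = np.tanh(a.data)
    out = Tensor(value, (a,))

    def backward(grad):
        a._accumulate(grad * (1.0 - value ** 2))

    out._backward = backward
    return out


def sigmoid(a: Tensor) -> Tensor:
    value = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))
    out = Tensor(value, (a,))

    def backward(grad):
        a._accumulate(grad * value * (1.0 - value))

    out._backward = backward
    return out


def relu(a: Tensor) -> Tensor:
    out = Tensor(np.maximum(a.data, 0.0), (a,))

    def backward(grad):
        a._accumulate(grad * (a.data > 0))

    out._backward = backward
    return out


def exp(a: Tensor) -> Tensor:
    value = np.exp(np.clip(a.data, -60, 60))
    out = Tensor(value, (a,))

    def backward(grad):
        a._accumulate(grad * value)

    out._backward = backward
    return out


def power(a: Tensor, exponent: float) -> Tensor:
    value = a.data ** exponent
    out = Tensor(value, (a,))

    def backward(grad):
        a._accumulate(grad * exponent * a.data ** (exponent - 1.0))

    out._backward = backward
    return out


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), (a,))

    def backward(grad):
        g = grad
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    out._backward = backward
    return out


def mean(a: Tensor) -> Tensor:
    n = a.data.size
    return mul(tsum(a), 1.0 / n)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            index = [slice(None)] * grad.ndim
            index[axis] = slice(lo, hi)
            t._accumulate(grad[tuple(index)])

    out._backward = backward
    return out


def column(a: Tensor, j: int) -> Tensor:
    """Select column ``j`` keeping two dimensions: (B, 1)."""
    out = Tensor(a.data[:, j:j + 1], (a,))

    def backward(grad):
        g = np.zeros_like(a.data)
        g[:, j:j + 1] = grad
        a._accumulate(g)

    out._backward = backward
    return out


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only where unclipped."""
    inside = (a.data > lo) & (a.data < hi)
    out = Tensor(np.clip(a.data, lo, hi), (a,))

    def backward(grad):
        a._accumulate(grad * inside)

    out._backward = backward
    return out


def arccos(a: Tensor) -> Tensor:
    value = np.arccos(np.clip(a.data, -1.0, 1.0))
    out = Tensor(value, (a,))

    def backward(grad):
        denom = np.sqrt(np.maximum(1.0 - a.data ** 2, 1e-12))
        a._accumulate(grad * (-1.0 / denom))

    out._backward = backward
    return out


def embedding(weight: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup (B,) -> (B, dim) with scatter-add gradient."""
    out = Tensor(weight.data[indices], (weight,))

    def backward(grad):
        g = np.zeros_like(weight.data)
        np.add.at(g, indices, grad)
        weight._accumulate(g)

    out._backward = backward
    return out


def softmax_rows(a: Tensor) -> Tensor:
    """Softmax along axis 1, numerically stabilised with a constant shift."""
    shifted = add(a, Tensor(-a.data.max(axis=1, keepdims=True)))
    e = exp(shifted)
    total = tsum(e, axis=1, keepdims=True)
    return mul(e, power(total, -1.0))


def dropout(a: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    if rate <= 0.0:
        return a
    keep = (rng.random(a.data.shape) >= rate) / (1.0 - rate)
    return mul(a, Tensor(keep))


# -- layers ----------------------------------------------------------------

def glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class Dense:
    def __init__(self, rng, n_in: int, n_out: int):
        self.W = Tensor(glorot(rng, n_in, n_out))
        self.b = Tensor(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.W), self.b)

    def parameters(self):
        return [self.W, self.b]


class GRUCell:
    """Standard gated recurrent unit: z/r gates and candidate state."""

    def __init__(self, rng, n_in: int, n_hidden: int):
        self.n_hidden = n_hidden
        self.Wz = Tensor(glorot(rng, n_in, n_hidden)); self.Uz = Tensor(glorot(rng, n_hidden, n_hidden)); self.bz = Tensor(np.zeros(n_hidden))
        self.Wr = Tensor(glorot(rng, n_in, n_hidden)); self.Ur = Tensor(glorot(rng, n_hidden, n_hidden)); self.br = Tensor(np.zeros(n_hidden))
        self.Wn = Tensor(glorot(rng, n_in, n_hidden)); self.Un = Tensor(glorot(rng, n_hidden, n_hidden)); self.bn = Tensor(np.zeros(n_hidden))

    def step(self, x: Tensor, h: Tensor) -> Tensor:
        z = sigmoid(add(add(matmul(x, self.Wz), matmul(h, self.Uz)), self.bz))
        r = sigmoid(add(add(matmul(x, self.Wr), matmul(h, self.Ur)), self.br))
        n = tanh(add(add(matmul(x, self.Wn), matmul(mul(r, h), self.Un)), self.bn))
        one_minus_z = add(mul(z, -1.0), 1.0)
        return add(mul(one_minus_z, n), mul(z, h))

    def run(self, xs: list[Tensor], reverse: bool = False) -> list[Tensor]:
        batch = xs[0].data.shape[0]
        h = Tensor(np.zeros((batch, self.n_hidden)))
        order = range(len(xs) - 1, -1, -1) if reverse else range(len(xs))
        out: dict[int, Tensor] = {}
        for t in order:
            h = self.step(xs[t], h)
            out[t] = h
        return [out[t] for t in range(len(xs))]

    def parameters(self):
        return [self.Wz, self.Uz, self.bz, self.Wr, self.Ur, self.br,
                self.Wn, self.Un, self.bn]


class BiGRU:
    """Bidirectional GRU; per-timestep outputs are forward/backward concat."""

    def __init__(self, rng, n_in: int, n_hidden: int):
        self.fwd = GRUCell(rng, n_in, n_hidden)
        self.bwd = GRUCell(rng, n_in, n_hidden)

    def run(self, xs: list[Tensor]) -> list[Tensor]:
        f = self.fwd.run(xs)
        b = self.bwd.run(xs, reverse=True)
        return [concat([ft, bt], axis=1) for ft, bt in zip(f, b)]

    def parameters(self):
        return self.fwd.parameters() + self.bwd.parameters()


class AdditiveAttention:
    """Additive attention producing softmax weights over timesteps."""

    def __init__(self, rng, n_in: int, n_hidden: int = 32):
        self.W = Tensor(glorot(rng, n_in, n_hidden))
        self.b = Tensor(np.zeros(n_hidden))
        self.v = Tensor(glorot(rng, n_hidden, 1))

    def weights(self, xs: list[Tensor]) -> Tensor:
        scores = [matmul(tanh(add(matmul(x, self.W), self.b)), self.v) for x in xs]
        return softmax_rows(concat(scores, axis=1))  # (B, T)

    def pool(self, xs: list[Tensor]) -> Tensor:
        alpha = self.weights(xs)
        pooled = None
        for t, x in enumerate(xs):
            term = mul(x, column(alpha, t))
            pooled = term if pooled is None else add(pooled, term)
        return pooled

    def parameters(self):
        return [self.W, self.b, self.v]


class Adam:
    def __init__(self, params: list[Tensor], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g ** 2
            m_hat = self.m[i] / (1 - self.beta1 ** self.t)
            v_hat = self.v[i] / (1 - self.beta2 ** self.t)
            p.data -= lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def masked_spectral_angle_loss(pred: Tensor, target: np.ndarray,
                               mask: np.ndarray) -> Tensor:
    """Mean (1 - spectral angle) over a batch, masked dims excluded.

    ``target`` must be >= 0 with masked dims at 0; ``mask`` is 0/1.  The
    cosine is clamped away from +/-1 so the gradient at a perfect prediction
    is exactly zero instead of undefined.
    """
    mask_t = Tensor(mask)
    p = mul(pred, mask_t)
    t = np.where(mask > 0, target, 0.0)
    dot = tsum(mul(p, Tensor(t)), axis=1, keepdims=True)
    norm_p = power(add(tsum(mul(p, p), axis=1, keepdims=True), 1e-12), 0.5)
    norm_t = np.sqrt((t ** 2).sum(axis=1, keepdims=True)) + 1e-12
    cosine = mul(mul(dot, power(norm_p, -1.0)), Tensor(1.0 / norm_t))
    angle = arccos(clip(cosine, -1.0 + 1e-7, 1.0 - 1e-7))
    return mean(mul(angle, 2.0 / math.pi))
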