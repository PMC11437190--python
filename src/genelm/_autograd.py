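"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the package's LSTM and transformer language
models: broadcasting arithmetic, matmul, the usual nonlinearities, softmax,
layer normalization, embedding lookup and a fused masked cross-entropy.
Gradients are accumulated in float64/float32 numpy arrays; correctness is
checked against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph -------------------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar root")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def bwd(g):
            self.grad += _unbroadcast(g, self.data.shape)
            other.grad += _unbroadcast(g, other.data.shape)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self.grad.__iadd__(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def bwd(g):
            self.grad += _unbroadcast(g * other.data, self.data.shape)
            other.grad += _unbroadcast(g * self.data, other.data.shape)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, (self, other))

        def bwd(g):
            self.grad += _unbroadcast(g / other.data, self.data.shape)
            other.grad += _unbroadcast(-g * self.data / other.data**2, other.data.shape)

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bwd(g):
            self.grad += _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape)
            other.grad += _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape)

        out._backward = bwd
        return out

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self.grad.__iadd__(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), (self,))
        out._backward = lambda g: self.grad.__iadd__(g.transpose(*inv))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], (self,))
        fancy = any(isinstance(k, (np.ndarray, list)) for k in (key if isinstance(key, tuple) else (key,)))

        def bwd(g):
            if fancy:
                np.add.at(self.grad, key, g)  # duplicate indices must accumulate
            else:
                self.grad[key] += g

        out._backward = bwd
        return out

    # -- nonlinearities -----------------------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, (self,))
        out._backward = lambda g: self.grad.__iadd__(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, (self,))
        out._backward = lambda g: self.grad.__iadd__(g * y * (1.0 - y))
        return out

    def relu(self):
        y = np.maximum(self.data, 0.0)
        out = Tensor(y, (self,))
        out._backward = lambda g: self.grad.__iadd__(g * (self.data > 0))
        return out

    def sum(self):
        out = Tensor(self.data.sum(), (self,))
        out._backward = lambda g: self.grad.__iadd__(np.broadcast_to(g, self.data.shape))
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, (self,))

        def bwd(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            self.grad += y * (g - dot)

        out._backward = bwd
        return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when ``rng`` is None (evaluation) or rate 0."""
    if rng is None or rate <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return x * keep


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), tuple(tensors))

    def bwd(g):
        pieces = np.split(g, len(tensors), axis=axis)
        for t, piece in zip(tensors, pieces):
            t.grad += np.squeeze(piece, axis=axis)

    out._backward = bwd
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t.grad += piece

    out._backward = bwd
    return out


def embedding(weight: Tensor, idx: np.ndarray) -> Tensor:
    """Row lookup ``weight[idx]`` with scatter-add gradients."""
    out = Tensor(weight.data[idx], (weight,))

    def bwd(g):
        np.add.at(weight.grad, idx, g)

    out._backward = bwd
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat * gamma.data + beta.data, (x, gamma, beta))
    d = x.data.shape[-1]

    def bwd(g):
        gamma.grad += _unbroadcast(g * xhat, gamma.data.shape)
        beta.grad += _unbroadcast(g, beta.data.shape)
        gx = g * gamma.data
        x.grad += inv * (gx - gx.mean(axis=-1, keepdims=True) - xhat * (gx * xhat).mean(axis=-1, keepdims=True))

    out._backward = bwd
    return out


def masked_nll(logits: Tensor, targets: np.ndarray, mask: np.ndarray) -> tuple[Tensor, int]:
    """Summed negative log-likelihood of ``targets`` under ``logits``.

    ``logits``: (..., V); ``targets``: integer array matching the leading
    shape; ``mask``: boolean, True where the position counts.  Returns the
    scalar total NLL (a graph node) and the number of masked-in positions.
    """
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - lse
    m = mask.astype(float)
    picked = np.take_along_axis(logp, targets[..., None], axis=-1)[..., 0]
    total = -(picked * m).sum()
    out = Tensor(total, (logits,))

    def bwd(g):
        grad = np.exp(logp)  # softmax probabilities
        np.put_along_axis(
            grad,
            targets[..., None],
            np.take_along_axis(grad, targets[..., None], axis=-1) - 1.0,
            axis=-1,
        )
        logits.grad += g * grad * m[..., None]

    out._backward = bwd
    return out, int(mask.sum())
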