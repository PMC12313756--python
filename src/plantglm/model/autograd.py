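"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for a small transformer encoder trained on CPU:
tensors hold float32 data, operations build a graph, and
:meth:`Tensor.backward` runs reverse accumulation in topological order.
Only the primitives the encoder needs are provided (matmul, broadcast
add/mul, reshape/transpose, softmax, layer norm, GELU, embedding lookup,
cross-entropy and mean-squared-error losses).
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "scale",
    "matmul",
    "reshape",
    "transpose",
    "take_position",
    "softmax_lastdim",
    "layer_norm",
    "gelu",
    "embedding",
    "cross_entropy_logits",
    "mse_loss",
    "Adam",
]


class Tensor:
    """A node in the computation graph wrapping a float32 ndarray."""

    __slots__ = ("data", "grad", "parents", "grad_fn", "requires_grad")

    def __init__(
        self,
        data: np.ndarray,
        parents: tuple["Tensor", ...] = (),
        grad_fn: Callable[[np.ndarray], tuple[np.ndarray | None, ...]] | None = None,
        requires_grad: bool = False,
    ) -> None:
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self.grad_fn = grad_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def backward(self) -> None:
        """Reverse-accumulate gradients from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS postorder (graphs can be deep)
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))

        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node.grad_fn is None or node.grad is None:
                continue
            grads = node.grad_fn(node.grad)
            for parent, g in zip(node.parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(np.float32, copy=True)
                else:
                    parent.grad += g

    def zero_grad(self) -> None:
        self.grad = None


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient down to the shape it was broadcast from."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data
    return Tensor(
        out_data,
        parents=(a, b),
        grad_fn=lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)),
    )


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data
    return Tensor(
        out_data,
        parents=(a, b),
        grad_fn=lambda g: (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        ),
    )


def scale(a: Tensor, c: float) -> Tensor:
    return Tensor(a.data * c, parents=(a,), grad_fn=lambda g: (g * c,))


def _swap_last2(x: np.ndarray) -> np.ndarray:
    return np.swapaxes(x, -1, -2)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = np.matmul(a.data, b.data)

    def grad_fn(g: np.ndarray):
        ga = _unbroadcast(np.matmul(g, _swap_last2(b.data)), a.data.shape)
        gb = _unbroadcast(np.matmul(_swap_last2(a.data), g), b.data.shape)
        return ga, gb

    return Tensor(out_data, parents=(a, b), grad_fn=grad_fn)


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    orig = a.data.shape
    return Tensor(
        a.data.reshape(shape), parents=(a,), grad_fn=lambda g: (g.reshape(orig),)
    )


def transpose(a: Tensor, axes: tuple[int, ...]) -> Tensor:
    inverse = tuple(np.argsort(axes))
    return Tensor(
        a.data.transpose(axes), parents=(a,), grad_fn=lambda g: (g.transpose(inverse),)
    )


def take_position(a: Tensor, position: int) -> Tensor:
    """Select one position along axis 1 of a (B, T, D) tensor."""

    def grad_fn(g: np.ndarray):
        full = np.zeros_like(a.data)
        full[:, position, :] = g
        return (full,)

    return Tensor(a.data[:, position, :], parents=(a,), grad_fn=grad_fn)


def softmax_lastdim(a: Tensor) -> Tensor:
    shifted = a.data - a.data.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=-1, keepdims=True)

    def grad_fn(g: np.ndarray):
        dot = (g * y).sum(axis=-1, keepdims=True)
        return (y * (g - dot),)

    return Tensor(y, parents=(a,), grad_fn=grad_fn)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    out = gamma.data * xhat + beta.data

    def grad_fn(g: np.ndarray):
        d = x.data.shape[-1]
        dxhat = g * gamma.data
        dx = inv_std * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )
        axes = tuple(range(g.ndim - 1))
        dgamma = (g * xhat).sum(axis=axes)
        dbeta = g.sum(axis=axes)
        return dx, dgamma, dbeta

    return Tensor(out, parents=(x, gamma, beta), grad_fn=grad_fn)


_GELU_C = math.sqrt(2.0 / math.pi)


def gelu(a: Tensor) -> Tensor:
    x = a.data
    inner = _GELU_C * (x + 0.044715 * x**3)
    t = np.tanh(inner)
    y = 0.5 * x * (1.0 + t)

    def grad_fn(g: np.ndarray):
        sech2 = 1.0 - t * t
        d_inner = _GELU_C * (1.0 + 3 * 0.044715 * x**2)
        dy = 0.5 * (1.0 + t) + 0.5 * x * sech2 * d_inner
        return (g * dy,)

    return Tensor(y, parents=(a,), grad_fn=grad_fn)


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    ids = np.asarray(ids)

    def grad_fn(g: np.ndarray):
        gt = np.zeros_like(table.data)
        np.add.at(gt, ids.reshape(-1), g.reshape(-1, g.shape[-1]))
        return (gt,)

    return Tensor(table.data[ids], parents=(table,), grad_fn=grad_fn)


def cross_entropy_logits(
    logits: Tensor, labels: np.ndarray, ignore_index: int = -100
) -> Tensor:
    """Mean cross-entropy over rows whose label is not ``ignore_index``.

    ``logits`` is (N, V); ``labels`` is (N,) integer.
    """
    labels = np.asarray(labels).reshape(-1)
    z = logits.data
    zmax = z.max(axis=-1, keepdims=True)
    logsumexp = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=-1))
    valid = labels != ignore_index
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no valid labels for cross-entropy")
    idx = np.where(valid)[0]
    nll = logsumexp[idx] - z[idx, labels[idx]]
    loss = nll.mean()

    def grad_fn(g: np.ndarray):
        p = np.exp(z - zmax)
        p /= p.sum(axis=-1, keepdims=True)
        gz = p
        gz[idx, labels[idx]] -= 1.0
        gz[~valid] = 0.0
        return (gz * (float(g) / n_valid),)

    return Tensor(np.float32(loss), parents=(logits,), grad_fn=grad_fn)


def mse_loss(pred: Tensor, targets: np.ndarray) -> Tensor:
    t = np.asarray(targets, dtype=np.float32).reshape(pred.data.shape)
    diff = pred.data - t
    loss = np.float32((diff**2).mean())

    def grad_fn(g: np.ndarray):
        return (float(g) * 2.0 * diff / diff.size,)

    return Tensor(loss, parents=(pred,), grad_fn=grad_fn)


class Adam:
    """Adam optimizer with bias correction and global-norm gradient clipping."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        max_grad_norm: float | None = 1.0,
    ) -> None:
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.max_grad_norm = max_grad_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def _clip_gradients(self) -> None:
        total = 0.0
        for p in self.params:
            if p.grad is not None:
                total += float((p.grad.astype(np.float64) ** 2).sum())
        norm = total**0.5
        if norm > self.max_grad_norm:
            scale = self.max_grad_norm / norm
            for p in self.params:
                if p.grad is not None:
                    p.grad *= scale

    def step(self) -> None:
        if self.max_grad_norm is not None:
            self._clip_gradients()
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
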