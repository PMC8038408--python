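"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the transformer autoencoder needs:
broadcasting elementwise arithmetic, batched matmul, ReLU, layer
normalization, softmax / log-softmax, embedding lookup, reshape /
transpose, reductions, and a fused token cross-entropy.  Gradients are
accumulated in float64 via a topologically sorted backward pass.

This is deliberately small: no in-place ops, no higher-order gradients,
no views.  Correctness is enforced by finite-difference checks in the
test suite rather than by generality.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add", "sub", "mul", "div", "neg", "matmul", "relu", "exp", "log",
    "power", "reshape", "transpose", "sum_", "mean_", "max_keepdims",
    "softmax", "log_softmax", "layer_norm", "embedding", "dropout_mask",
    "cross_entropy_tokens", "constant",
]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None):
        """Run reverse-mode accumulation from this node."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("implicit backward requires a scalar output")
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    # convenience operator sugar
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x) -> Tensor:
    """A graph leaf that never requires gradient."""
    return Tensor(x, requires_grad=False)


def _sum_to(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to the shape of its source."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_sum_to(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_sum_to(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_sum_to(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_sum_to(-g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_sum_to(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_sum_to(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_sum_to(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_sum_to(-g * a.data / (b.data ** 2), b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def neg(a: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(-g)

    return Tensor(-a.data, parents=(a,), backward=backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product with numpy broadcasting over leading dims."""
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_sum_to(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_sum_to(gb, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return Tensor(out_data, parents=(a,), backward=backward)


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data)

    return Tensor(out_data, parents=(a,), backward=backward)


def log(a: Tensor) -> Tensor:
    out_data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    return Tensor(out_data, parents=(a,), backward=backward)


def power(a: Tensor, p: float) -> Tensor:
    out_data = a.data ** p

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * p * a.data ** (p - 1))

    return Tensor(out_data, parents=(a,), backward=backward)


def reshape(a: Tensor, shape) -> Tensor:
    orig = a.data.shape
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(orig))

    return Tensor(out_data, parents=(a,), backward=backward)


def transpose(a: Tensor, axes) -> Tensor:
    out_data = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.transpose(g, inv))

    return Tensor(out_data, parents=(a,), backward=backward)


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return Tensor(out_data, parents=(a,), backward=backward)


def mean_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(sum_(a, axis=axis, keepdims=keepdims), constant(1.0 / n))


def max_keepdims(a: Tensor, axis: int) -> Tensor:
    """Max along an axis, treated as a constant (no gradient flows).

    Used only for numerical stabilization of softmax-style expressions,
    where subtracting any constant leaves the value and gradient intact.
    """
    return constant(a.data.max(axis=axis, keepdims=True))


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accumulate(out_data * (g - dot))

    return Tensor(out_data, parents=(a,), backward=backward)


def log_softmax(a: Tensor, axis: int = -1) -> Tensor:
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse
    soft = np.exp(out_data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g - soft * g.sum(axis=axis, keepdims=True))

    return Tensor(out_data, parents=(a,), backward=backward)


def layer_norm(a: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Normalization over the last axis with learned scale and shift."""
    mu = a.data.mean(axis=-1, keepdims=True)
    var = a.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (a.data - mu) * inv
    out_data = xhat * gamma.data + beta.data

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate(_sum_to(g * xhat, gamma.data.shape))
        if beta.requires_grad:
            beta._accumulate(_sum_to(g, beta.data.shape))
        if a.requires_grad:
            n = a.data.shape[-1]
            gx = g * gamma.data
            a._accumulate(inv / n * (
                n * gx
                - gx.sum(axis=-1, keepdims=True)
                - xhat * (gx * xhat).sum(axis=-1, keepdims=True)))

    return Tensor(out_data, parents=(a, gamma, beta), backward=backward)


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup weight[ids]; gradient scatters back into the table."""
    ids = np.asarray(ids, dtype=np.int64)
    out_data = weight.data[ids]

    def backward(g):
        if weight.requires_grad:
            gw = np.zeros_like(weight.data)
            np.add.at(gw, ids.reshape(-1),
                      g.reshape(-1, weight.data.shape[-1]))
            weight._accumulate(gw)

    return Tensor(out_data, parents=(weight,), backward=backward)


def dropout_mask(a: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when rate == 0."""
    if rate <= 0.0:
        return a
    keep = 1.0 - rate
    mask = (rng.random(a.data.shape) < keep) / keep
    return mul(a, constant(mask))


def cross_entropy_tokens(logits: Tensor, targets: np.ndarray,
                         weights: np.ndarray) -> Tensor:
    """Weighted mean token NLL from raw logits.

    logits: (..., L, V); targets: integer (..., L); weights: (..., L)
    nonnegative position weights (0 masks pads).  Returns a scalar.
    """
    lsm = log_softmax(logits, axis=-1)
    targets = np.asarray(targets, dtype=np.int64)
    onehot = np.zeros(lsm.data.shape)
    grid = np.indices(targets.shape)
    onehot[(*grid, targets)] = 1.0
    w = np.asarray(weights, dtype=np.float64)
    total = w.sum()
    if total <= 0:
        raise ValueError("cross_entropy_tokens: all positions masked")
    picked = sum_(mul(lsm, constant(onehot)), axis=-1)
    return mul(sum_(mul(picked, constant(w))), constant(-1.0 / total))
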