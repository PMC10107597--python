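"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operator set the model graph needs: broadcast
arithmetic, tensordot-style dense contractions, strided 2-D and 1-D
convolution, ReLU, axis softmax, axis max, reshape and concatenation.
Everything is float64; gradients are accumulated on leaf tensors marked
``requires_grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "add",
    "mul",
    "sub",
    "div",
    "relu",
    "exp",
    "sqrt",
    "square",
    "reshape",
    "concat",
    "tsum",
    "amax",
    "softmax",
    "dense",
    "conv2d",
    "conv1d",
    "softmax_cross_entropy",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- convenience -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- operator sugar ----------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __neg__(self):
        return mul(self, Tensor(-1.0))

    # -- backprop ----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise ValueError("called backward on a tensor without requires_grad")
        if grad is None:
            if self.data.size != 1:
                raise ValueError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if not parent.requires_grad:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg
            if node._backward is None:  # leaf
                node.grad = g if node.grad is None else node.grad + g


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(data) -> Tensor:
    return Tensor(data)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


# ---------------------------------------------------------------------------
# elementwise
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        return ((a, _unbroadcast(g, a.shape)), (b, _unbroadcast(g, b.shape)))

    return Tensor(out_data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def backward(g):
        return ((a, _unbroadcast(g, a.shape)), (b, _unbroadcast(-g, b.shape)))

    return Tensor(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        return (
            (a, _unbroadcast(g * b.data, a.shape)),
            (b, _unbroadcast(g * a.data, b.shape)),
        )

    return Tensor(out_data, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data / b.data

    def backward(g):
        return (
            (a, _unbroadcast(g / b.data, a.shape)),
            (b, _unbroadcast(-g * a.data / (b.data ** 2), b.shape)),
        )

    return Tensor(out_data, (a, b), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g):
        return ((a, g * mask),)

    return Tensor(out_data, (a,), backward)


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def backward(g):
        return ((a, g * out_data),)

    return Tensor(out_data, (a,), backward)


def sqrt(a: Tensor) -> Tensor:
    out_data = np.sqrt(a.data)

    def backward(g):
        return ((a, g * 0.5 / np.where(out_data == 0, np.inf, out_data)),)

    return Tensor(out_data, (a,), backward)


def square(a: Tensor) -> Tensor:
    out_data = a.data ** 2

    def backward(g):
        return ((a, g * 2.0 * a.data),)

    return Tensor(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    old_shape = a.shape
    out_data = a.data.reshape(shape)

    def backward(g):
        return ((a, g.reshape(old_shape)),)

    return Tensor(out_data, (a,), backward)


def concat(tensors, axis: int) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, pieces))

    return Tensor(out_data, tuple(tensors), backward)


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return ((a, np.broadcast_to(g, a.shape).copy()),)
        gg = g
        if not keepdims:
            gg = np.expand_dims(g, axis)
        return ((a, np.broadcast_to(gg, a.shape).copy()),)

    return Tensor(out_data, (a,), backward)


def amax(a: Tensor, axis, keepdims: bool = True) -> Tensor:
    """Max along axes; ties share the gradient equally."""
    out_data = a.data.max(axis=axis, keepdims=True)
    hit = (a.data == out_data).astype(np.float64)
    hit /= hit.sum(axis=axis, keepdims=True)
    res = out_data if keepdims else np.squeeze(out_data, axis=axis)

    def backward(g):
        gg = g if keepdims else np.expand_dims(g, axis)
        return ((a, gg * hit),)

    return Tensor(res, (a,), backward)


def softmax(a: Tensor, axis: int) -> Tensor:
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        return ((a, out_data * (g - dot)),)

    return Tensor(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# contractions and convolutions
# ---------------------------------------------------------------------------

def dense(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Affine map over the last axis: ``y = x @ w + b``."""
    out_data = x.data @ w.data
    if b is not None:
        out_data = out_data + b.data

    def backward(g):
        grads = [
            (x, g @ w.data.T),
            (w, np.tensordot(x.data, g, axes=(tuple(range(x.ndim - 1)),) * 2)),
        ]
        if b is not None:
            grads.append((b, _unbroadcast(g, b.shape)))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents, backward)


def _pad_same(n: int, k: int, stride: int) -> tuple[int, int]:
    out = -(-n // stride)  # ceil
    total = max((out - 1) * stride + k - n, 0)
    return total // 2, total - total // 2


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """'Same'-padded 2-D convolution.

    x: (B, H, W, Cin); w: (kh, kw, Cin, Cout); output (B, Ho, Wo, Cout)
    with Ho = ceil(H / stride).
    """
    bsz, hh, ww, cin = x.shape
    kh, kw, cin_w, cout = w.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, kernel {cin_w}")
    pt, pb = _pad_same(hh, kh, stride)
    pl, pr = _pad_same(ww, kw, stride)
    xp = np.pad(x.data, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    ho = -(-hh // stride)
    wo = -(-ww // stride)
    out_data = np.zeros((bsz, ho, wo, cout))
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, i : i + stride * ho : stride, j : j + stride * wo : stride, :]
            out_data += np.tensordot(patch, w.data[i, j], axes=([3], [0]))
    if b is not None:
        out_data += b.data

    def backward(g):
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(w.data)
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, i : i + stride * ho : stride, j : j + stride * wo : stride, :]
                dw[i, j] = np.tensordot(patch, g, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, i : i + stride * ho : stride, j : j + stride * wo : stride, :] += np.tensordot(
                    g, w.data[i, j], axes=([3], [1])
                )
        dx = dxp[:, pt : pt + hh, pl : pl + ww, :]
        grads = [(x, dx), (w, dw)]
        if b is not None:
            grads.append((b, _unbroadcast(g, b.shape)))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents, backward)


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """'Same'-padded 1-D convolution.

    x: (B, L, Cin); w: (k, Cin, Cout); output (B, Lo, Cout).
    """
    bsz, ll, cin = x.shape
    k, cin_w, cout = w.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, kernel {cin_w}")
    pl, pr = _pad_same(ll, k, stride)
    xp = np.pad(x.data, ((0, 0), (pl, pr), (0, 0)))
    lo = -(-ll // stride)
    out_data = np.zeros((bsz, lo, cout))
    for i in range(k):
        out_data += np.tensordot(xp[:, i : i + stride * lo : stride, :], w.data[i], axes=([2], [0]))
    if b is not None:
        out_data += b.data

    def backward(g):
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(w.data)
        for i in range(k):
            patch = xp[:, i : i + stride * lo : stride, :]
            dw[i] = np.tensordot(patch, g, axes=([0, 1], [0, 1]))
            dxp[:, i : i + stride * lo : stride, :] += np.tensordot(g, w.data[i], axes=([2], [1]))
        dx = dxp[:, pl : pl + ll, :]
        grads = [(x, dx), (w, dw)]
        if b is not None:
            grads.append((b, _unbroadcast(g, b.shape)))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents, backward)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of softmax(logits) against integer labels."""
    labels = np.asarray(labels)
    n = logits.shape[0]
    shifted = logits.data - logits.data.max(axis=1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    logp = shifted - logz
    loss = -logp[np.arange(n), labels].mean()

    def backward(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        return ((logits, g * p / n),)

    return Tensor(loss, (logits,), backward)
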