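"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the compute core the gated multi-view network is built on: a small
tape-based engine supporting exactly the operations the model needs
(broadcasted arithmetic, matmul, reductions, sigmoid/exp/log, clipping with
zero gradient in the clipped region, slicing/stacking, and a strided 2-D
convolution).  Gradients are accumulated by topological traversal of the
recorded graph.

Arrays are kept in float64 throughout; the models here are small enough that
precision is worth more than speed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "sigmoid", "softmax", "relu", "conv2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape machinery for reverse-mode gradients."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    # -- graph plumbing ------------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients into every reachable tensor with requires_grad."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed needs a scalar output")
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in node._backward(g):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg
            if node is self or not node._parents:
                node.grad = g if node.grad is None else node.grad + g

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return ((self, _unbroadcast(g, self.data.shape)),
                    (other, _unbroadcast(g, other.data.shape)))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            return ((self, -g),)
        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return ((self, _unbroadcast(g * other.data, self.data.shape)),
                    (other, _unbroadcast(g * self.data, other.data.shape)))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            return ((self, _unbroadcast(g / other.data, self.data.shape)),
                    (other, _unbroadcast(-g * self.data / other.data ** 2,
                                         other.data.shape)))

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            return ((self, g * exponent * self.data ** (exponent - 1)),)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return ((self, _unbroadcast(ga, a.shape)),
                    (other, _unbroadcast(gb, b.shape)))

        return Tensor._make(out_data, (self, other), backward)

    # -- shape ops -----------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            return ((self, g.reshape(old)),)

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            return ((self, g.transpose(inv)),)

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, index):
        out_data = self.data[index]
        shape = self.data.shape

        def backward(g):
            full = np.zeros(shape, dtype=np.float64)
            np.add.at(full, index, g)
            return ((self, full),)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            if axis is None:
                return ((self, np.broadcast_to(g, shape).copy()),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return ((self, np.broadcast_to(g, shape).copy()),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return ((self, g * out_data),)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            return ((self, g / self.data),)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            return ((self, g * out_data * (1.0 - out_data)),)

        return Tensor._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            return ((self, g * (1.0 - out_data ** 2)),)

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            return ((self, g * mask),)

        return Tensor._make(self.data * mask, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clip to [lo, hi]; gradient is zero in the clipped region."""
        inside = (self.data > lo) & (self.data < hi)

        def backward(g):
            return ((self, g * inside),)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    def sqrt(self):
        return self ** 0.5


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def sigmoid(x: Tensor) -> Tensor:
    return as_tensor(x).sigmoid()


def relu(x: Tensor) -> Tensor:
    return as_tensor(x).relu()


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Stack tensors of identical shape along a new axis."""
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        pieces = np.split(g, len(tensors), axis=axis)
        return tuple((t, np.squeeze(p, axis=axis))
                     for t, p in zip(tensors, pieces))

    return Tensor._make(out_data, tuple(tensors), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # shift by a detached max: values and gradients match exact softmax
    shifted = x - np.max(x.data, axis=axis, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def _im2col_indices(in_shape, kh, kw, stride):
    _, _, h, w = in_shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    i0 = np.repeat(np.arange(kh), kw)
    j0 = np.tile(np.arange(kw), kh)
    i1 = stride * np.repeat(np.arange(oh), ow)
    j1 = stride * np.tile(np.arange(ow), oh)
    rows = i0[:, None] + i1[None, :]        # (kh*kw, oh*ow)
    cols = j0[:, None] + j1[None, :]
    return rows, cols, oh, ow


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1) -> Tensor:
    """Valid-mode strided 2-D convolution: x (B,C,H,W), weight (O,C,kh,kw)."""
    x = as_tensor(x)
    weight = as_tensor(weight)
    bias = as_tensor(bias)
    B, C, H, W = x.shape
    O, _, kh, kw = weight.shape
    rows, cols, oh, ow = _im2col_indices(x.shape, kh, kw, stride)
    # patches: (B, C, kh*kw, oh*ow)
    patches = x.data[:, :, rows, cols]
    pmat = patches.reshape(B, C * kh * kw, oh * ow)
    wmat = weight.data.reshape(O, C * kh * kw)
    out_data = (wmat @ pmat).reshape(B, O, oh, ow) + bias.data[None, :, None, None]

    def backward(g):
        gmat = g.reshape(B, O, oh * ow)
        gw = np.einsum("bop,bkp->ok", gmat, pmat).reshape(weight.shape)
        gb = g.sum(axis=(0, 2, 3))
        gp = np.einsum("ok,bop->bkp", wmat, gmat).reshape(B, C, kh * kw, oh * ow)
        gx = np.zeros((B, C, H, W), dtype=np.float64)
        np.add.at(gx, (slice(None), slice(None), rows, cols), gp)
        return ((x, gx), (weight, gw), (bias, gb))

    return Tensor._make(out_data, (x, weight, bias), backward)
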