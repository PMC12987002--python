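"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float32 numpy array and records the operation graph
when gradients are enabled; :meth:`Tensor.backward` runs reverse-mode
accumulation over a topological sort of the graph.  The op set is exactly
what the fusion U-Nets and the transformer/CNN backbones in this package
need: broadcast arithmetic, (batched) matmul, shape ops, stride-1
convolution via im2col, depthwise convolution, 2x2 max-pooling, nearest
up-sampling, softmax / GELU / sigmoid / ReLU, reductions, roll, and row
gather.  Convolutions reduce to BLAS matmuls through
``numpy.lib.stride_tricks.sliding_window_view``.
"""

from __future__ import annotations

import contextlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import special

__all__ = ["Tensor", "no_grad", "concat"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        needs = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=needs)
        if needs:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            stack = [(node, False)]
            while stack:
                n, processed = stack.pop()
                if processed:
                    topo.append(n)
                    continue
                if id(n) in seen or n._backward is None:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                stack.extend((p, False) for p in n._parents)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            node._backward(node.grad)
            if node is not self:
                node.grad = None  # free intermediate gradients

    # -- conveniences ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        a, b = self, Tensor.as_tensor(other)

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._result(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(-g)

        return Tensor._result(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor.as_tensor(other)

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._result(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor.as_tensor(other)

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor._result(a.data / b.data, (a, b), backward)

    def __pow__(self, exponent: float):
        a = self
        out_data = a.data ** exponent

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * exponent * a.data ** (exponent - 1.0))

        return Tensor._result(out_data, (a,), backward)

    def __matmul__(self, other):
        a, b = self, Tensor.as_tensor(other)

        def backward(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accumulate(_unbroadcast(gb, b.shape))

        return Tensor._result(np.matmul(a.data, b.data), (a, b), backward)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape

        def backward(g):
            if a.requires_grad:
                a._accumulate(g.reshape(old))

        return Tensor._result(a.data.reshape(shape), (a,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inverse = np.argsort(axes)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g.transpose(inverse))

        return Tensor._result(a.data.transpose(axes), (a,), backward)

    def __getitem__(self, key):
        a = self

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, key, g)
                a._accumulate(full)

        return Tensor._result(a.data[key], (a,), backward)

    def roll(self, shift, axis):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(np.roll(g, tuple(-s for s in shift), axis))

        return Tensor._result(np.roll(a.data, shift, axis), (a,), backward)

    def take_rows(self, indices: np.ndarray):
        """Row gather ``self[indices]`` for an integer index array."""
        a = self
        idx = np.asarray(indices)

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx.reshape(-1), g.reshape(-1, *a.shape[1:]))
                a._accumulate(full)

        return Tensor._result(a.data[idx], (a,), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.shape).copy())

        return Tensor._result(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- pointwise nonlinearities -------------------------------------------
    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * mask)

        return Tensor._result(a.data * mask, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = special.expit(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._result(out_data, (a,), backward)

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        a = self
        x = a.data.astype(np.float64)
        phi = 0.5 * (1.0 + special.erf(x / np.sqrt(2.0)))

        def backward(g):
            if a.requires_grad:
                pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
                a._accumulate(g * (phi + x * pdf).astype(np.float32))

        return Tensor._result((x * phi).astype(np.float32), (a,), backward)

    def softmax(self, axis: int = -1):
        a = self
        shifted = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if a.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                a._accumulate(out_data * (g - dot))

        return Tensor._result(out_data, (a,), backward)

    def sqrt(self):
        return self ** 0.5

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * out_data)

        return Tensor._result(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(g / a.data)

        return Tensor._result(np.log(a.data), (a,), backward)

    # -- spatial ops (NCHW) -------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None, padding: int = 0):
        """Stride-1 cross-correlation; ``weight`` is (O, C, kh, kw)."""
        a, w = self, weight
        kh, kw = w.shape[2], w.shape[3]
        xp = np.pad(a.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        windows = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,C,Ho,Wo,kh,kw
        out_data = np.tensordot(windows, w.data, axes=([1, 4, 5], [1, 2, 3]))
        out_data = np.ascontiguousarray(out_data.transpose(0, 3, 1, 2))
        if bias is not None:
            out_data += bias.data[None, :, None, None]
        parents = (a, w) if bias is None else (a, w, bias)

        def backward(g):
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                gw = np.tensordot(g, windows, axes=([0, 2, 3], [0, 2, 3]))
                w._accumulate(gw)
            if a.requires_grad:
                # full correlation of the padded gradient with the flipped kernel
                wf = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # C,O,kh,kw
                gp = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
                gwin = sliding_window_view(gp, (kh, kw), axis=(2, 3))
                gxp = np.tensordot(gwin, wf, axes=([1, 4, 5], [1, 2, 3]))
                gxp = gxp.transpose(0, 3, 1, 2)
                h, wdt = a.shape[2], a.shape[3]
                a._accumulate(gxp[:, :, padding:padding + h, padding:padding + wdt])

        return Tensor._result(out_data, parents, backward)

    def depthwise_conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
                         padding: int = 0):
        """Per-channel stride-1 cross-correlation; ``weight`` is (C, kh, kw)."""
        a, w = self, weight
        kh, kw = w.shape[1], w.shape[2]
        xp = np.pad(a.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        windows = sliding_window_view(xp, (kh, kw), axis=(2, 3))
        out_data = np.einsum("nchwuv,cuv->nchw", windows, w.data, optimize=True)
        if bias is not None:
            out_data += bias.data[None, :, None, None]
        parents = (a, w) if bias is None else (a, w, bias)

        def backward(g):
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                w._accumulate(np.einsum("nchw,nchwuv->cuv", g, windows, optimize=True))
            if a.requires_grad:
                wf = w.data[:, ::-1, ::-1]
                gp = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
                gwin = sliding_window_view(gp, (kh, kw), axis=(2, 3))
                gxp = np.einsum("nchwuv,cuv->nchw", gwin, wf, optimize=True)
                h, wdt = a.shape[2], a.shape[3]
                a._accumulate(gxp[:, :, padding:padding + h, padding:padding + wdt])

        return Tensor._result(out_data, parents, backward)

    def maxpool2x2(self):
        a = self
        n, c, h, w = a.shape
        if h % 2 or w % 2:
            raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
        blocks = a.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        blocks = blocks.reshape(n, c, h // 2, w // 2, 4)
        arg = blocks.argmax(axis=-1)
        out_data = np.take_along_axis(blocks, arg[..., None], axis=-1)[..., 0]

        def backward(g):
            if not a.requires_grad:
                return
            gb = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
            np.put_along_axis(gb, arg[..., None], g[..., None], axis=-1)
            gb = gb.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            a._accumulate(gb.reshape(n, c, h, w))

        return Tensor._result(np.ascontiguousarray(out_data), (a,), backward)

    def upsample_nearest2x(self):
        a = self
        n, c, h, w = a.shape
        out_data = a.data.repeat(2, axis=2).repeat(2, axis=3)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

        return Tensor._result(out_data, (a,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, stop)
                t._accumulate(g[tuple(sl)])

    return Tensor._result(np.concatenate([t.data for t in tensors], axis=axis),
                          tensors, backward)
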