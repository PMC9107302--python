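"""Minimal reverse-mode automatic differentiation on numpy arrays.

The network layers in this package are plain tensor algebra (matrix
products, gather/scatter over graph edges, segment reductions, ReLU
family nonlinearities).  This module provides exactly those primitives
as a :class:`Tensor` wrapper around ``numpy.ndarray`` with a recorded
computation graph and a topological-order backward pass.  Everything is
float64 and CPU-only; there is no broadcasting magic beyond numpy's own,
and gradients of broadcast operands are reduced back to their shape.

Only what the layers need is implemented; this is a numerical core, not
a general framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "segment_sum", "segment_max", "segment_softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # ------------------------------------------------------------------
    # arithmetic
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))
        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def _bw():
            if self.requires_grad:
                self._accum(-out.grad)
        out._backward = _bw
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))
        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(
                    -out.grad * self.data / other.data ** 2, other.data.shape))
        out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))

        def _bw():
            if self.requires_grad:
                with np.errstate(divide="ignore", invalid="ignore"):
                    d = exponent * self.data ** (exponent - 1)
                # subgradient 0 at poles (e.g. d/dx sqrt(x) at x = 0)
                d = np.where(np.isfinite(d), d, 0.0)
                self._accum(out.grad * d)
        out._backward = _bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw():
            if self.requires_grad:
                g = out.grad @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                g = np.swapaxes(self.data, -1, -2) @ out.grad
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = _bw
        return out

    # ------------------------------------------------------------------
    # elementwise nonlinearities
    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * out.data)
        out._backward = _bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad / self.data)
        out._backward = _bw
        return out

    def sqrt(self):
        return self ** 0.5

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * mask)
        out._backward = _bw
        return out

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)
        out = Tensor(self.data * factor, self.requires_grad, (self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * factor)
        out._backward = _bw
        return out

    # ------------------------------------------------------------------
    # reductions and shaping
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def _bw():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Channel-wise maximum; ties split the gradient evenly."""
        m = self.data.max(axis=axis, keepdims=True)
        out_data = m if keepdims else np.squeeze(m, axis=axis)
        out = Tensor(out_data, self.requires_grad, (self,))

        def _bw():
            if self.requires_grad:
                mask = (self.data == m)
                counts = mask.sum(axis=axis, keepdims=True)
                g = out.grad if keepdims else np.expand_dims(out.grad, axis)
                self._accum(mask * (g / counts))
        out._backward = _bw
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))
        out._backward = _bw
        return out

    def take(self, index, axis: int = 0):
        """Gather along ``axis`` with an integer index array.

        Backward scatter-adds into the source, so repeated indices
        accumulate — this is what makes it usable as embedding lookup
        and edge-endpoint gather.
        """
        index = np.asarray(index, dtype=np.intp)
        out = Tensor(np.take(self.data, index, axis=axis),
                     self.requires_grad, (self,))

        def _bw():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                idx = (slice(None),) * axis + (index,)
                np.add.at(g, idx, out.grad)
                self._accum(g)
        out._backward = _bw
        return out

    def dropout(self, rate: float, rng: np.random.Generator):
        """Inverted dropout; call only during training."""
        if rate <= 0:
            return self
        keep = (rng.random(self.data.shape) >= rate) / (1.0 - rate)
        return self * Tensor(keep)

    def detach(self) -> np.ndarray:
        return self.data

    # ------------------------------------------------------------------
    def backward(self) -> None:
        """Reverse pass from this (scalar or any-shape) tensor."""
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()


# ----------------------------------------------------------------------
# free functions


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def _bw():
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = (slice(None),) * axis + (slice(a, b),)
                t._accum(out.grad[sl])
    out._backward = _bw
    return out


def segment_sum(x: Tensor, seg: np.ndarray, num_segments: int) -> Tensor:
    """Row-wise sum of ``x`` into ``num_segments`` buckets given by ``seg``."""
    seg = np.asarray(seg, dtype=np.intp)
    data = np.zeros((num_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(data, seg, x.data)
    out = Tensor(data, x.requires_grad, (x,))

    def _bw():
        if x.requires_grad:
            x._accum(out.grad[seg])
    out._backward = _bw
    return out


def segment_max(x: Tensor, seg: np.ndarray, num_segments: int,
                fill: float = -np.inf) -> Tensor:
    """Channel-wise maximum per segment; empty segments get ``fill``.

    Gradient is split evenly across rows tying for the maximum.
    """
    seg = np.asarray(seg, dtype=np.intp)
    data = np.full((num_segments,) + x.data.shape[1:], fill, dtype=np.float64)
    np.maximum.at(data, seg, x.data)
    out = Tensor(data, x.requires_grad, (x,))

    def _bw():
        if x.requires_grad:
            mask = (x.data == data[seg])
            counts = np.zeros_like(data)
            np.add.at(counts, seg, mask.astype(np.float64))
            counts = np.maximum(counts, 1.0)
            x._accum(mask * (out.grad / counts)[seg])
    out._backward = _bw
    return out


def segment_softmax(x: Tensor, seg: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of rows of ``x`` normalized within each segment.

    The per-segment maximum shift is a detached constant (it cancels in
    the softmax gradient), which keeps the computation stable for large
    inverse temperatures.
    """
    seg = np.asarray(seg, dtype=np.intp)
    shift = np.full((num_segments,) + x.data.shape[1:], -np.inf)
    np.maximum.at(shift, seg, x.data)
    shift[~np.isfinite(shift)] = 0.0  # empty segments
    z = (x - Tensor(shift[seg])).exp()
    denom = segment_sum(z, seg, num_segments)
    # guard empty segments; no row maps to them so the value is unused
    denom = denom + Tensor((denom.data == 0).astype(np.float64))
    return z / denom.take(seg)
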