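"""Minimal reverse-mode automatic differentiation on numpy arrays.

The networks in this package are small convolutional models trained on CPU,
so the engine implements exactly the operator set they need: broadcasted
arithmetic, convolution, instance statistics, piecewise-linear activations,
spatial padding/cropping/upsampling and channel concatenation.  Gradients
are accumulated by a tape of closures and released after ``backward``.

All image tensors are NCHW ``float64`` unless the caller passes float32;
dtype is preserved through every op.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64 if not isinstance(data, np.ndarray) else data.dtype)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or not g.flags.owndata else g
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None):
        """Backpropagate from this tensor (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() on non-scalar requires an explicit gradient")
            grad = np.ones_like(self.data)
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if not node.requires_grad and node._backward is not None:
                node.grad = None  # free intermediate grads
            node._backward = None
            node._parents = ()

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other))
        out = Tensor(self.data + other.data)
        out._parents = (self, other)

        def _bw(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data)
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other))
        out = Tensor(self.data - other.data)
        out._parents = (self, other)

        def _bw(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(-g, other.data.shape))

        out._backward = _bw
        return out

    def __rsub__(self, other):
        return Tensor(np.asarray(other)) - self

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other))
        out = Tensor(self.data * other.data)
        out._parents = (self, other)

        def _bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * (1.0 / other)

    def __pow__(self, p: float):
        out = Tensor(self.data ** p)
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        out._parents = (self,)

        def _bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).astype(self.data.dtype))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).astype(self.data.dtype))

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise nonlinearities --------------------------------------

    def abs(self):
        out = Tensor(np.abs(self.data))
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(g * np.sign(self.data))
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y)
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(g * (1.0 - y * y))
        return out

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, slope * self.data))
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(g * np.where(mask, 1.0, slope))
        return out

    def relu(self):
        return self.leaky_relu(0.0)

    # -- shape ops --------------------------------------------------------

    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape))
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(g.reshape(orig))
        return out

    def pad2d(self, top: int, bottom: int, left: int, right: int):
        """Zero-pad the two trailing (spatial) axes."""
        pad = [(0, 0)] * (self.data.ndim - 2) + [(top, bottom), (left, right)]
        out = Tensor(np.pad(self.data, pad))
        out._parents = (self,)
        h, w = self.data.shape[-2:]

        def _bw(g):
            self._accumulate(g[..., top:top + h, left:left + w])

        out._backward = _bw
        return out

    def crop_batch(self, start: int, count: int):
        """Slice along the leading (batch) axis."""
        out = Tensor(self.data[start:start + count])
        out._parents = (self,)

        def _bw(g):
            gg = np.zeros_like(self.data)
            gg[start:start + count] = g
            self._accumulate(gg)

        out._backward = _bw
        return out

    def crop2d(self, top: int, left: int, height: int, width: int):
        out = Tensor(self.data[..., top:top + height, left:left + width])
        out._parents = (self,)

        def _bw(g):
            gg = np.zeros_like(self.data)
            gg[..., top:top + height, left:left + width] = g
            self._accumulate(gg)

        out._backward = _bw
        return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    out._parents = tuple(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    out._backward = _bw
    return out


def _im2col(xt: np.ndarray, kh: int, kw: int, stride: int):
    """NHWC array -> (N*Ho*Wo, kh*kw*C) patch matrix; contiguous gathers."""
    win = sliding_window_view(xt, (kh, kw), axis=(1, 2))[:, ::stride, ::stride]
    Ho, Wo = win.shape[1], win.shape[2]
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        -1, kh * kw * xt.shape[3])
    return cols, Ho, Wo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW x OCkk -> NOHW, zero padding.

    Forward and both backward passes are GEMMs on channels-last patch
    matrices; the input gradient is a full correlation with the spatially
    flipped, channel-transposed kernel (zero-stuffed when strided), and
    is skipped entirely for constant leaf inputs.
    """
    N, C, H, W = x.data.shape
    O, C2, kh, kw = w.data.shape
    if C != C2:
        raise ValueError(f"channel mismatch: input {C} vs weight {C2}")
    dtype = np.result_type(x.data.dtype, w.data.dtype)
    xt = np.ascontiguousarray(x.data.transpose(0, 2, 3, 1))  # NHWC
    if padding:
        xt = np.pad(xt, ((0, 0), (padding, padding), (padding, padding), (0, 0)))
    if kh > xt.shape[1] or kw > xt.shape[2]:
        raise ValueError("kernel larger than (padded) input")
    cols, Ho, Wo = _im2col(xt, kh, kw, stride)
    w2 = np.ascontiguousarray(w.data.transpose(0, 2, 3, 1)).reshape(O, kh * kw * C)
    if w2.dtype != dtype:
        w2 = w2.astype(dtype)
    y = cols @ w2.T  # (N*Ho*Wo, O)
    if b is not None:
        y = y + b.data.astype(dtype)
    out = Tensor(np.ascontiguousarray(
        y.reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2)))
    out._parents = (x, w) if b is None else (x, w, b)
    x_needs_grad = x.requires_grad or x._backward is not None

    def _bw(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, O)
        dw2 = g2.T @ cols  # (O, kh*kw*C)
        w._accumulate(dw2.reshape(O, kh, kw, C).transpose(0, 3, 1, 2))
        if b is not None:
            b._accumulate(g2.sum(axis=0))
        if not x_needs_grad:
            return
        gt = g2.reshape(N, Ho, Wo, O)
        if stride > 1:
            gd = np.zeros((N, stride * (Ho - 1) + 1, stride * (Wo - 1) + 1, O),
                          dtype=dtype)
            gd[:, ::stride, ::stride] = gt
        else:
            gd = gt
        pl_h, pl_w = kh - 1 - padding, kw - 1 - padding
        pr_h = H + kh - 1 - pl_h - gd.shape[1]
        pr_w = W + kw - 1 - pl_w - gd.shape[2]
        gp = np.pad(gd, ((0, 0), (pl_h, pr_h), (pl_w, pr_w), (0, 0)))
        wt = np.ascontiguousarray(
            w.data[:, :, ::-1, ::-1].transpose(1, 2, 3, 0)).reshape(C, kh * kw * O)
        if wt.dtype != dtype:
            wt = wt.astype(dtype)
        gcols, Hh, Wwidth = _im2col(gp, kh, kw, 1)
        dx = (gcols @ wt.T).reshape(N, Hh, Wwidth, C)
        x._accumulate(np.ascontiguousarray(dx.transpose(0, 3, 1, 2)))

    out._backward = _bw
    return out


def _linear_resize_axis(x: Tensor, length_out: int, axis: int) -> Tensor:
    """Bilinear (1-D linear, half-pixel centers) resize along one axis."""
    length_in = x.data.shape[axis]
    src = (np.arange(length_out) + 0.5) * (length_in / length_out) - 0.5
    f = np.floor(src)
    t = src - f
    i0 = np.clip(f, 0, length_in - 1).astype(np.intp)
    i1 = np.clip(f + 1, 0, length_in - 1).astype(np.intp)
    shp = [1] * x.data.ndim
    shp[axis] = length_out
    t = t.reshape(shp)
    y = np.take(x.data, i0, axis=axis) * (1 - t) + np.take(x.data, i1, axis=axis) * t
    out = Tensor(y)
    out._parents = (x,)

    def _bw(g):
        gg = np.zeros_like(x.data)
        gm = np.moveaxis(gg, axis, 0)
        gsrc = np.moveaxis(g, axis, 0)
        tt = np.moveaxis(np.broadcast_to(t, g.shape), axis, 0)
        np.add.at(gm, i0, gsrc * (1 - tt))
        np.add.at(gm, i1, gsrc * tt)
        x._accumulate(gg)

    out._backward = _bw
    return out


def upsample2d(x: Tensor, factor: int, mode: str = "bilinear") -> Tensor:
    """Upsample the spatial axes of an NCHW tensor by an integer factor."""
    if factor == 1:
        return x
    if mode == "nearest":
        y = np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3)
        out = Tensor(y)
        out._parents = (x,)
        N, C, H, W = x.data.shape

        def _bw(g):
            g = g.reshape(N, C, H, factor, W, factor).sum(axis=(3, 5))
            x._accumulate(g)

        out._backward = _bw
        return out
    if mode == "bilinear":
        h, w = x.data.shape[2] * factor, x.data.shape[3] * factor
        return _linear_resize_axis(_linear_resize_axis(x, h, 2), w, 3)
    if mode == "zeros":  # zero-stuffing, the front half of a transposed conv
        N, C, H, W = x.data.shape
        y = np.zeros((N, C, H * factor, W * factor), dtype=x.data.dtype)
        y[:, :, ::factor, ::factor] = x.data
        out = Tensor(y)
        out._parents = (x,)
        out._backward = lambda g: x._accumulate(g[:, :, ::factor, ::factor])
        return out
    raise ValueError(f"unknown upsample mode {mode!r}")
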