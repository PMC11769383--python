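"""Reverse-mode automatic differentiation on numpy arrays.

A small tensor engine in the micrograd style, sized for encoder–decoder
segmentation networks: elementwise arithmetic with broadcasting, batched
matmul, 2-D convolution (grouped / depthwise), pooling, bilinear
upsampling, and the activations the blocks use (ReLU, GELU, sigmoid,
softplus, softmax).  Gradients are accumulated by a topological sweep over
the recorded graph.

The engine is dtype-agnostic: float32 is the training default, float64 is
used by the finite-difference gradient checks.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf, expit

__all__ = [
    "Tensor",
    "concatenate",
    "conv2d",
    "maxpool2x2",
    "upsample_bilinear2x",
    "matmul",
    "relu",
    "gelu",
    "sigmoid",
    "softplus",
    "softmax",
    "no_grad",
]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph recording (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make `ndarray op Tensor` defer to the reflected Tensor operator
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        if self.data.dtype.kind not in "fc":
            self.data = self.data.astype(np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph bookkeeping -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- shape utilities ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src_shape = self.data.shape
        out = Tensor._make(
            self.data.reshape(shape),
            (self,),
            lambda g: self._accum(g.reshape(src_shape)),
        )
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes),
            (self,),
            lambda g: self._accum(g.transpose(inv)),
        )

    def __getitem__(self, idx):
        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(p, (slice, int)) for p in parts)

        def backward(g):
            gx = np.zeros_like(self.data)
            if basic:
                gx[idx] += g  # basic indexing never aliases
            else:
                np.add.at(gx, idx, g)
            self._accum(gx)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _coerce(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = Tensor._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: self._accum(-g))

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, p: float):
        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), backward)

    def __matmul__(self, other):
        return matmul(self, other)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        src_shape = self.data.shape

        def backward(g):
            if axis is None:
                gx = np.broadcast_to(g, src_shape)
            else:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                axes = tuple(a % len(src_shape) for a in axes)
                if not keepdims:
                    g = np.expand_dims(g, axes)
                gx = np.broadcast_to(g, src_shape)
            self._accum(gx.copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise functions ---------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: self._accum(g * out_data))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: self._accum(g / self.data))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._make(out_data, (self,), lambda g: self._accum(g / (2.0 * out_data)))


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a = Tensor._coerce(a)
    b = Tensor._coerce(b)

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.data.shape))

    return Tensor._make(a.data @ b.data, (a, b), backward)


def concatenate(tensors, axis: int = 1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x._accum(g * mask)

    return Tensor._make(np.where(mask, x.data, 0.0), (x,), backward)


_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    cdf = 0.5 * (1.0 + erf(x.data * _INV_SQRT2))

    def backward(g):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x.data**2)
        x._accum(g * (cdf + x.data * pdf))

    return Tensor._make(x.data * cdf, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    y = expit(x.data)

    def backward(g):
        x._accum(g * y * (1.0 - y))

    return Tensor._make(y, (x,), backward)


def softplus(x: Tensor) -> Tensor:
    """log(1 + e^x), computed stably for large |x|."""

    def backward(g):
        x._accum(g * expit(x.data))

    return Tensor._make(np.logaddexp(0.0, x.data), (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # computed in place: the attention matrix can dominate peak memory
    y = x.data - x.data.max(axis=axis, keepdims=True)
    np.exp(y, out=y)
    y /= y.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accum(y * (g - dot))

    return Tensor._make(y, (x,), backward)


# ---------------------------------------------------------------------------
# structured ops
# ---------------------------------------------------------------------------


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, square stride/padding.

    `groups == in_channels` with one filter per channel gives a depthwise
    convolution.  Stride-1 convolutions use a shift-and-GEMM decomposition
    (one BLAS call per kernel tap, no im2col copy); strided ones fall back
    to an im2col matrix.
    """
    N, Cin, H, W = x.data.shape
    Cout, Cg, kh, kw = w.data.shape
    if Cin % groups or Cout % groups or Cg != Cin // groups:
        raise ValueError(
            f"conv2d channel mismatch: input {Cin}, weight {w.data.shape}, groups {groups}"
        )
    if groups not in (1, Cin) or (groups == Cin and Cout != Cin and groups != 1):
        if groups != 1 and not (groups == Cin and Cout == Cin):
            raise ValueError("only groups=1 or depthwise (groups=Cin=Cout) supported")
    s, p = stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Hp, Wp = xp.shape[2:]
    Ho, Wo = (Hp - kh) // s + 1, (Wp - kw) // s + 1
    depthwise = groups != 1

    if s == 1 and not depthwise:
        acc = None
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i : i + Ho, j : j + Wo]
                t = np.tensordot(w.data[:, :, i, j], xs, axes=(1, 1))  # (Cout,N,Ho,Wo)
                acc = t if acc is None else acc + t
        out = acc.transpose(1, 0, 2, 3)

        def backward(g):
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)).reshape(b.data.shape))
            if w.requires_grad:
                gw = np.empty_like(w.data)
                for i in range(kh):
                    for j in range(kw):
                        xs = xp[:, :, i : i + Ho, j : j + Wo]
                        gw[:, :, i, j] = np.tensordot(g, xs, axes=([0, 2, 3], [0, 2, 3]))
                w._accum(gw)
            if x.requires_grad:
                gxp = np.zeros((N, Cin, Hp, Wp), dtype=g.dtype)
                for i in range(kh):
                    for j in range(kw):
                        t = np.tensordot(w.data[:, :, i, j], g, axes=(0, 1))
                        gxp[:, :, i : i + Ho, j : j + Wo] += t.transpose(1, 0, 2, 3)
                x._accum(gxp[:, :, p : Hp - p, p : Wp - p] if p else gxp)

    elif s == 1 and depthwise:
        wd = w.data.reshape(Cin, kh, kw)
        out = np.zeros((N, Cin, Ho, Wo), dtype=x.data.dtype)
        for i in range(kh):
            for j in range(kw):
                out += wd[:, i, j][None, :, None, None] * xp[:, :, i : i + Ho, j : j + Wo]

        def backward(g):
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)).reshape(b.data.shape))
            if w.requires_grad:
                gw = np.empty_like(wd)
                for i in range(kh):
                    for j in range(kw):
                        gw[:, i, j] = (g * xp[:, :, i : i + Ho, j : j + Wo]).sum(axis=(0, 2, 3))
                w._accum(gw.reshape(w.data.shape))
            if x.requires_grad:
                gxp = np.zeros((N, Cin, Hp, Wp), dtype=g.dtype)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i : i + Ho, j : j + Wo] += g * wd[:, i, j][None, :, None, None]
                x._accum(gxp[:, :, p : Hp - p, p : Wp - p] if p else gxp)

    else:
        cols = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
        og, ig = Cout // groups, Cin // groups
        colg = cols.reshape(N, groups, ig, Ho, Wo, kh, kw)
        wg = w.data.reshape(groups, og, ig, kh, kw)
        out = np.einsum("goikl,ngihwkl->ngohw", wg, colg,
                        optimize=True).reshape(N, Cout, Ho, Wo)

        def backward(g):
            gg = g.reshape(N, groups, og, Ho, Wo)
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)).reshape(b.data.shape))
            if w.requires_grad:
                gw = np.einsum("ngohw,ngihwkl->goikl", gg, colg, optimize=True)
                w._accum(gw.reshape(Cout, ig, kh, kw))
            if x.requires_grad:
                gcol = np.einsum("ngohw,goikl->ngihwkl", gg, wg, optimize=True)
                gcol = gcol.reshape(N, Cin, Ho, Wo, kh, kw)
                gxp = np.zeros((N, Cin, Hp, Wp), dtype=g.dtype)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += gcol[:, :, :, :, i, j]
                x._accum(gxp[:, :, p : Hp - p, p : Wp - p] if p else gxp)

    if b is not None:
        out = out + b.data.reshape(1, Cout, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def maxpool2x2(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2x2 needs even spatial size, got {H}x{W}")
    xr = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(N, C, H // 2, W // 2, 4)
    arg = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        gr = np.zeros((N, C, H // 2, W // 2, 4), dtype=g.dtype)
        np.put_along_axis(gr, arg[..., None], g[..., None], axis=-1)
        gr = gr.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accum(gr.reshape(N, C, H, W))

    return Tensor._make(out, (x,), backward)


def _linear_axis_weights(n_out: int, n_in: int, dtype):
    """Source indices / weights for 2x bilinear resampling along one axis."""
    src = (np.arange(n_out, dtype=dtype) + 0.5) / 2.0 - 0.5
    i0 = np.clip(np.floor(src).astype(np.intp), 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    t = np.clip(src - np.floor(src), 0.0, 1.0)
    t = np.where(src < 0, 0.0, np.where(src > n_in - 1, 1.0, t))
    return i0, i1, t.astype(dtype)


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Doubles H and W with bilinear interpolation (half-pixel centers)."""
    N, C, H, W = x.data.shape
    dt = x.data.dtype
    r0, r1, tr = _linear_axis_weights(2 * H, H, dt)
    c0, c1, tc = _linear_axis_weights(2 * W, W, dt)
    tr_ = tr[:, None]
    rows = x.data[:, :, r0, :] * (1 - tr_) + x.data[:, :, r1, :] * tr_
    out = rows[:, :, :, c0] * (1 - tc) + rows[:, :, :, c1] * tc

    def backward(g):
        grows = np.zeros((N, C, 2 * H, W), dtype=g.dtype)
        np.add.at(grows, (slice(None), slice(None), slice(None), c0), g * (1 - tc))
        np.add.at(grows, (slice(None), slice(None), slice(None), c1), g * tc)
        gx = np.zeros((N, C, H, W), dtype=g.dtype)
        np.add.at(gx, (slice(None), slice(None), r0), grows * (1 - tr_))
        np.add.at(gx, (slice(None), slice(None), r1), grows * tr_)
        x._accum(gx)

    return Tensor._make(out, (x,), backward)
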