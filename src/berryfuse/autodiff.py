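"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine provides exactly the operations the fusion network needs:
elementwise arithmetic with broadcasting, matrix multiplication, 2-D
convolution (dense and depthwise) implemented as im2col + GEMM, max
pooling, batch normalization, reductions, and the usual pointwise
nonlinearities.  Gradients are accumulated by walking the recorded
computation graph in reverse topological order.

Tensors preserve the dtype of the array they wrap (float32 for training,
float64 wherever tests want tight numerical agreement).
"""

from __future__ import annotations

import contextlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (inference / analysis passes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = ()
        self._backward = None

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, dtype={self.dtype}, requires_grad={self.requires_grad})"

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other, self.dtype)

        def bw(g, a=self, b=other):
            a._accum(_unbroadcast(g, a.shape))
            b._accum(_unbroadcast(g, b.shape))

        return _make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g, a=self):
            a._accum(-g)

        return _make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return _as_tensor(other, self.dtype) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other, self.dtype)

        def bw(g, a=self, b=other):
            a._accum(_unbroadcast(g * b.data, a.shape))
            b._accum(_unbroadcast(g * a.data, b.shape))

        return _make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other, self.dtype)

        def bw(g, a=self, b=other):
            a._accum(_unbroadcast(g / b.data, a.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return _make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return _as_tensor(other, self.dtype) / self

    def __pow__(self, p: float):
        def bw(g, a=self):
            a._accum(g * p * a.data ** (p - 1))

        return _make(self.data**p, (self,), bw)

    def __matmul__(self, other):
        other = _as_tensor(other, self.dtype)

        def bw(g, a=self, b=other):
            a._accum(g @ b.data.T)
            b._accum(a.data.T @ g)

        return _make(self.data @ other.data, (self, other), bw)

    # -- reductions & shaping --------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g, a=self):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.shape).astype(a.dtype))

        return _make(out, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(g, a=self):
            a._accum(g.reshape(a.shape))

        return _make(self.data.reshape(shape), (self,), bw)

    def __getitem__(self, key):
        def bw(g, a=self):
            full = np.zeros_like(a.data)
            np.add.at(full, key, g)
            a._accum(full)

        return _make(self.data[key], (self,), bw)

    def max(self, axis: int, keepdims: bool = False):
        """Max over one axis; gradient routed to the (first) argmax."""
        idx = np.expand_dims(self.data.argmax(axis=axis), axis)
        out = np.take_along_axis(self.data, idx, axis=axis)

        def bw(g, a=self):
            gg = g if keepdims else np.expand_dims(g, axis)
            full = np.zeros_like(a.data)
            np.put_along_axis(full, idx, gg, axis=axis)
            a._accum(full)

        return _make(out if keepdims else np.squeeze(out, axis), (self,), bw)

    # -- pointwise nonlinearities ----------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g, a=self):
            a._accum(g * mask)

        return _make(self.data * mask, (self,), bw)

    def sigmoid(self):
        out = _sigmoid(self.data)

        def bw(g, a=self):
            a._accum(g * out * (1.0 - out))

        return _make(out, (self,), bw)

    def softplus(self):
        out = np.logaddexp(0.0, self.data).astype(self.dtype)

        def bw(g, a=self):
            a._accum(g * _sigmoid(a.data))

        return _make(out, (self,), bw)

    def exp(self):
        out = np.exp(self.data)

        def bw(g, a=self):
            a._accum(g * out)

        return _make(out, (self,), bw)

    def log(self):
        def bw(g, a=self):
            a._accum(g / a.data)

        return _make(np.log(self.data), (self,), bw)

    def sqrt(self):
        out = np.sqrt(self.data)

        def bw(g, a=self):
            a._accum(g * 0.5 / out)

        return _make(out, (self,), bw)

    def abs(self):
        sign = np.sign(self.data)

        def bw(g, a=self):
            a._accum(g * sign)

        return _make(np.abs(self.data), (self,), bw)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _as_tensor(x, dtype=np.float32) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _make(data: np.ndarray, parents: tuple, backward_fn) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward_fn
    return out


# ---------------------------------------------------------------------------
# structural ops
# ---------------------------------------------------------------------------

def concat(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g, ts=tensors):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


def stack_mean(tensors) -> Tensor:
    """Mean of same-shaped scalar tensors (used for loss averaging)."""
    n = len(tensors)
    acc = tensors[0]
    for t in tensors[1:]:
        acc = acc + t
    return acc * (1.0 / n)


# ---------------------------------------------------------------------------
# convolution / pooling
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int,
            ph_l: int, ph_r: int, pw_l: int, pw_r: int):
    xp = np.pad(x, ((0, 0), (0, 0), (ph_l, ph_r), (pw_l, pw_r)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, ho, wo = win.shape[:4]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * ho * wo, c * kh * kw)
    return cols, ho, wo


def _col2im(dct: np.ndarray, x_shape: tuple, kh: int, kw: int,
            stride: int, padding: int) -> np.ndarray:
    """Scatter-add patch gradients (C*kh*kw, N*Ho*Wo) back onto the input."""
    n, c, h, w = x_shape
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (w + 2 * padding - kw) // stride + 1
    dv = dct.reshape(c, kh, kw, n, ho, wo)
    xp = np.zeros((n, c, h + 2 * padding, w + 2 * padding), dtype=dct.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride] += \
                dv[:, i, j].transpose(1, 0, 2, 3)
    if padding:
        xp = xp[:, :, padding:padding + h, padding:padding + w]
    return np.ascontiguousarray(xp)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, square stride/padding."""
    n, ci, h, wdt = x.shape
    co, ci_w, kh, kw = w.shape
    if ci != ci_w:
        raise ValueError(f"conv2d channel mismatch: input {ci}, weight {ci_w}")
    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding, padding, padding, padding)
    out = cols @ w.data.reshape(co, -1).T
    if b is not None:
        out += b.data
    out = out.reshape(n, ho, wo, co).transpose(0, 3, 1, 2)

    def bw(g, xt=x, wt=w, bt=b):
        gmt = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(co, -1)
        wt._accum((gmt @ cols).reshape(wt.shape))
        if bt is not None:
            bt._accum(gmt.sum(axis=1))
        if xt.requires_grad or xt._parents:
            dct = wt.data.reshape(co, -1).T @ gmt  # (Ci*kh*kw, N*Ho*Wo)
            xt._accum(_col2im(dct, xt.shape, kh, kw, stride, padding))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, bw)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     padding: int = 1) -> Tensor:
    """Per-channel (depthwise) 2-D convolution, stride 1."""
    n, c, h, wdt = x.shape
    cw, kh, kw = w.shape
    if c != cw:
        raise ValueError(f"depthwise channel mismatch: input {c}, weight {cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    out = np.einsum("nchwij,cij->nchw", win, w.data, optimize=True)
    if b is not None:
        out += b.data[:, None, None]

    def bw(g, xt=x, wt=w, bt=b):
        wt._accum(np.einsum("nchwij,nchw->cij", win, g, optimize=True))
        if bt is not None:
            bt._accum(g.sum(axis=(0, 2, 3)))
        if xt.requires_grad or xt._parents:
            gp = np.pad(g, ((0, 0), (0, 0), (kh - 1 - padding,) * 2, (kw - 1 - padding,) * 2))
            gwin = sliding_window_view(gp, (kh, kw), axis=(2, 3))
            wflip = wt.data[:, ::-1, ::-1]
            xt._accum(np.einsum("nchwij,cij->nchw", gwin, wflip, optimize=True))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, bw)


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    n, c, h, w = x.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2),
                constant_values=-np.inf)
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    flat = win.reshape(n, c, ho, wo, kernel * kernel)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bw(g, xt=x):
        ii = np.arange(ho)[:, None] * stride - padding + (idx // kernel)
        jj = np.arange(wo)[None, :] * stride - padding + (idx % kernel)
        nn = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, :, None, None]
        full = np.zeros_like(xt.data)
        np.add.at(full, (nn, cc, ii, jj), g)
        xt._accum(full)

    return _make(np.ascontiguousarray(out), (x,), bw)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) mean over spatial dims."""
    n, c, h, w = x.shape
    out = x.data.mean(axis=(2, 3))

    def bw(g, xt=x):
        xt._accum(np.broadcast_to(g[:, :, None, None] / (h * w), xt.shape).astype(xt.dtype))

    return _make(out, (x,), bw)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    n, c, h, w = x.shape
    m = n * h * w
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var * (m / max(m - 1, 1))  # unbiased for running stats
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[:, None, None]) * inv_std[:, None, None]
    out = gamma.data[:, None, None] * xhat + beta.data[:, None, None]

    def bw(g, xt=x, gt=gamma, bt=beta):
        gt._accum(np.einsum("nchw,nchw->c", g, xhat, optimize=True))
        bt._accum(g.sum(axis=(0, 2, 3)))
        if xt.requires_grad or xt._parents:
            dxhat = g * gt.data[:, None, None]
            if training:
                t1 = dxhat.mean(axis=(0, 2, 3))
                t2 = (dxhat * xhat).mean(axis=(0, 2, 3))
                gx = inv_std[:, None, None] * (
                    dxhat - t1[:, None, None] - xhat * t2[:, None, None]
                )
            else:
                gx = dxhat * inv_std[:, None, None]
            xt._accum(gx.astype(xt.dtype))

    return _make(out.astype(x.dtype), (x, gamma, beta), bw)
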