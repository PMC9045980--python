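"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine provides exactly the operator set the segmentation networks need:
broadcast elementwise arithmetic, matrix products, reductions, slicing,
sigmoid/tanh, channel softmax, and fused image ops (2-D convolution with
dilation, stride-2 transposed convolution, 2x2 max pooling, global spatial
max, group normalization, PReLU).  Tensors are NCHW; all ops run at the dtype
of their inputs, so float64 gradient checks and float32 training share one
code path.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "group_norm",
    "matmul",
    "max_pool2d",
    "prelu",
    "sigmoid",
    "softmax_channels",
    "spatial_max",
    "tanh",
    "tmean",
    "tsum",
]


class Tensor:
    """An array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(other, ref: "Tensor") -> "Tensor":
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=ref.data.dtype))

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autodiff core --------------------------------------------------------

    def backward(self, grad=None):
        """Backpropagate from this tensor (scalar unless ``grad`` is given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)

        # DFS post-order gives a topological ordering of the graph.
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- operators ------------------------------------------------------------

    def __add__(self, other):
        return _add(self, self._lift(other, self))

    __radd__ = __add__

    def __neg__(self):
        return _scale(self, -1.0)

    def __sub__(self, other):
        return _add(self, _scale(self._lift(other, self), -1.0))

    def __rsub__(self, other):
        return _add(self._lift(other, self), _scale(self, -1.0))

    def __mul__(self, other):
        return _mul(self, self._lift(other, self))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _div(self, self._lift(other, self))

    def __rtruediv__(self, other):
        return _div(self._lift(other, self), self)

    def __getitem__(self, key):
        return _getitem(self, key)

    def reshape(self, *shape):
        return _reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, g):
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.asarray(g, dtype=t.data.dtype).copy()
    else:
        t.grad += g


def _unbroadcast(g, shape):
    """Sum ``g`` down to ``shape`` (reverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- elementwise --------------------------------------------------------------


def _add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), backward)


def _scale(a: Tensor, s: float) -> Tensor:
    def backward(g):
        _accum(a, s * g)

    return _make(a.data * s, (a,), backward)


def _mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), backward)


def _div(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accum(a, _unbroadcast(g / b.data, a.data.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return _make(a.data / b.data, (a, b), backward)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        _accum(x, g * y * (1.0 - y))

    return _make(y, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)

    def backward(g):
        _accum(x, g * (1.0 - y * y))

    return _make(y, (x,), backward)


def prelu(x: Tensor, slope: Tensor) -> Tensor:
    """PReLU with a per-channel slope; channel axis is 1 for 4-D inputs.

    ``slope`` has shape (C,) (or a single element) and is broadcast over the
    remaining axes.
    """
    s = slope.data
    if x.data.ndim == 4:
        s_b = s.reshape(1, -1, 1, 1) if s.size > 1 else s.reshape(1, 1, 1, 1)
    elif x.data.ndim == 2:
        s_b = s.reshape(1, -1) if s.size > 1 else s.reshape(1, 1)
    else:
        s_b = s
    neg = np.minimum(x.data, 0)
    y = np.maximum(x.data, 0) + s_b * neg

    def backward(g):
        dx = np.where(x.data > 0, g, g * s_b)
        _accum(x, dx)
        gs = g * neg
        if x.data.ndim == 4:
            axes = (0, 2, 3) if s.size > 1 else (0, 1, 2, 3)
        elif x.data.ndim == 2:
            axes = (0,) if s.size > 1 else (0, 1)
        else:
            axes = tuple(range(x.data.ndim))
        _accum(slope, gs.sum(axis=axes).reshape(slope.data.shape))

    return _make(y, (x, slope), backward)


# -- shape / reductions --------------------------------------------------------


def _reshape(x: Tensor, shape) -> Tensor:
    old = x.data.shape

    def backward(g):
        _accum(x, g.reshape(old))

    return _make(x.data.reshape(shape), (x,), backward)


def _getitem(x: Tensor, key) -> Tensor:
    parts = key if isinstance(key, tuple) else (key,)
    advanced = any(isinstance(p, (np.ndarray, list)) for p in parts)

    def backward(g):
        dz = np.zeros_like(x.data)
        if advanced:  # repeated indices must accumulate
            np.add.at(dz, key, g)
        else:
            dz[key] += g
        _accum(x, dz)

    return _make(x.data[key], (x,), backward)


def tsum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    def backward(g):
        if axis is None:
            _accum(x, np.broadcast_to(g, x.data.shape))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accum(x, np.broadcast_to(g, x.data.shape))

    return _make(x.data.sum(axis=axis, keepdims=keepdims), (x,), backward)


def tmean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = x.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([x.data.shape[a] for a in axes]))
    return _scale(tsum(x, axis=axis, keepdims=keepdims), 1.0 / n)


def concat(tensors, axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D matrix product ``a @ b``."""

    def backward(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    return _make(a.data @ b.data, (a, b), backward)


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over axis 1 of an NCHW tensor."""
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=1, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=1, keepdims=True)
        _accum(x, y * (g - dot))

    return _make(y, (x,), backward)


# -- fused image operators -----------------------------------------------------


def _im2col(xp, k, d, H, W):
    N, C = xp.shape[:2]
    cols = np.empty((N, C, k * k, H, W), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i * k + j] = xp[:, :, i * d : i * d + H, j * d : j * d + W]
    return cols.reshape(N, C * k * k, H * W)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1) -> Tensor:
    """Stride-1 'same' 2-D convolution (cross-correlation), NCHW.

    ``w`` has shape (out, in, k, k); zero padding d*(k-1)/2 preserves the
    spatial size for odd k at any dilation.
    """
    N, C, H, W = x.data.shape
    O, _, k, _ = w.data.shape
    d = dilation
    pad = d * (k - 1) // 2
    if k == 1:
        cols = x.data.reshape(N, C, H * W)
    else:
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        cols = _im2col(xp, k, d, H, W)
    W2 = w.data.reshape(O, -1)
    out = np.matmul(W2, cols)  # (N, O, H*W)
    if b is not None:
        out += b.data.reshape(1, O, 1)
    out = out.reshape(N, O, H, W)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        go = g.reshape(N, O, H * W)
        if b is not None:
            _accum(b, go.sum(axis=(0, 2)))
        dW2 = np.matmul(go, cols.transpose(0, 2, 1)).sum(axis=0)
        _accum(w, dW2.reshape(w.data.shape))
        if x.requires_grad:
            dcols = np.matmul(W2.T, go)  # (N, C*k*k, H*W)
            if k == 1:
                _accum(x, dcols.reshape(N, C, H, W))
            else:
                dc = dcols.reshape(N, C, k * k, H, W)
                Hp, Wp = H + 2 * pad, W + 2 * pad
                dxp = np.zeros((N, C, Hp, Wp), dtype=x.data.dtype)
                for i in range(k):
                    for j in range(k):
                        dxp[:, :, i * d : i * d + H, j * d : j * d + W] += dc[:, :, i * k + j]
                _accum(x, dxp[:, :, pad : pad + H, pad : pad + W])

    return _make(out, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2x2 stride-2 transposed convolution (the decoder upsampler).

    ``w`` has shape (in, out, 2, 2); output spatial dims are doubled.
    """
    N, C, H, W = x.data.shape
    _, O = w.data.shape[:2]
    x2 = x.data.reshape(N, C, H * W)
    W2 = w.data.reshape(C, O * 4)
    y = np.matmul(W2.T, x2)  # (N, O*4, H*W)
    y = y.reshape(N, O, 2, 2, H, W).transpose(0, 1, 4, 2, 5, 3).reshape(N, O, 2 * H, 2 * W)
    if b is not None:
        y = y + b.data.reshape(1, O, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if b is not None:
            _accum(b, g.sum(axis=(0, 2, 3)))
        g6 = g.reshape(N, O, H, 2, W, 2).transpose(0, 1, 3, 5, 2, 4).reshape(N, O * 4, H * W)
        dW2 = np.matmul(x2, g6.transpose(0, 2, 1)).sum(axis=0)  # (C, O*4)
        _accum(w, dW2.reshape(w.data.shape))
        if x.requires_grad:
            dx = np.matmul(W2, g6)  # (N, C, H*W)
            _accum(x, dx.reshape(N, C, H, W))

    return _make(y, parents, backward)


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 stride-2 max pooling; spatial dims must be even."""
    N, C, H, W = x.data.shape
    H2, W2 = H // 2, W // 2
    xw = x.data.reshape(N, C, H2, 2, W2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H2, W2, 4)
    idx = xw.argmax(axis=-1)
    out = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dxw = np.zeros_like(xw)
        np.put_along_axis(dxw, idx[..., None], g[..., None], axis=-1)
        dx = dxw.reshape(N, C, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W)
        _accum(x, dx)

    return _make(out, (x,), backward)


def spatial_max(x: Tensor) -> Tensor:
    """Global max pooling: (N, C, H, W) -> (N, C)."""
    N, C, H, W = x.data.shape
    flat = x.data.reshape(N, C, H * W)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
        _accum(x, dflat.reshape(N, C, H, W))

    return _make(out, (x,), backward)


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int, eps: float = 1e-5) -> Tensor:
    """Group normalization over an NCHW tensor with per-channel affine."""
    N, C, H, W = x.data.shape
    G = groups
    xg = x.data.reshape(N, G, -1)
    mu = xg.mean(axis=-1, keepdims=True)
    var = xg.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xg - mu) * inv
    xhat4 = xhat.reshape(N, C, H, W)
    y = xhat4 * gamma.data.reshape(1, C, 1, 1) + beta.data.reshape(1, C, 1, 1)

    def backward(g):
        _accum(gamma, (g * xhat4).sum(axis=(0, 2, 3)))
        _accum(beta, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxhat = (g * gamma.data.reshape(1, C, 1, 1)).reshape(N, G, -1)
            m1 = dxhat.mean(axis=-1, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
            dx = inv * (dxhat - m1 - xhat * m2)
            _accum(x, dx.reshape(N, C, H, W))

    return _make(y, (x, gamma, beta), backward)
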