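"""Reverse-mode automatic differentiation over numpy float32 arrays.

A deliberately small engine carrying exactly the operations the
super-resolution networks need: 3D convolution, dense layers, leaky ReLU,
sigmoid / log / softplus, reshapes and permutations, concatenation, 2D max
pooling, and a trilinear depth upsampler.  Gradients are accumulated on leaf
tensors marked ``requires_grad``; a :func:`no_grad` context disables graph
construction for inference so large forward passes keep no activations.
"""
from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction -----------------------------------------------------
    @staticmethod
    def _node(data, parents, backward_fn) -> "Tensor":
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out = Tensor(data, requires_grad=True)
            out._parents = tuple(parents)
            out._backward = backward_fn
            return out
        return Tensor(data)

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- backward pass -----------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        # iterative topological order (graphs are hundreds of nodes deep)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                # leaf: accumulate
                if node.grad is None:
                    node.grad = g.astype(np.float32, copy=True)
                else:
                    node.grad += g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, neg(_wrap(other)))

    def __rsub__(self, other):
        return add(_wrap(other), neg(self))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def reshape(self, shape):
        return reshape(self, shape)

    def transpose(self, axes):
        return transpose(self, axes)

    def sum(self):
        return sum_(self)

    def mean(self):
        return mean(self)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- elementwise / linear algebra ------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def bwd(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return Tensor._node(out, (a, b), bwd)


def neg(a: Tensor) -> Tensor:
    return Tensor._node(-a.data, (a,), lambda g: (-g,))


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data

    def bwd(g):
        return (_unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape))

    return Tensor._node(out, (a, b), bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data @ b.data

    def bwd(g):
        return g @ b.data.T, a.data.T @ g

    return Tensor._node(out, (a, b), bwd)


def square(a: Tensor) -> Tensor:
    return Tensor._node(a.data * a.data, (a,), lambda g: (2.0 * g * a.data,))


def log(a: Tensor) -> Tensor:
    return Tensor._node(np.log(a.data), (a,), lambda g: (g / a.data,))


def _expit(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit
    return expit(x).astype(np.float32)


def sigmoid(a: Tensor) -> Tensor:
    s = _expit(a.data)
    return Tensor._node(s, (a,), lambda g: (g * s * (1.0 - s),))


def softplus(a: Tensor) -> Tensor:
    """log(1 + exp(x)), numerically stable."""
    x = a.data
    out = np.logaddexp(0.0, x)

    def bwd(g):
        return (g * _expit(x),)

    return Tensor._node(out, (a,), bwd)


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    mask = a.data > 0
    out = np.where(mask, a.data, slope * a.data)

    def bwd(g):
        return (np.where(mask, g, np.float32(slope) * g),)

    return Tensor._node(out, (a,), bwd)


def relu(a: Tensor) -> Tensor:
    return leaky_relu(a, 0.0)


# -- reductions -------------------------------------------------------------

def sum_(a: Tensor) -> Tensor:
    def bwd(g):
        return (np.broadcast_to(g, a.data.shape).astype(np.float32),)

    return Tensor._node(a.data.sum(), (a,), bwd)


def mean(a: Tensor) -> Tensor:
    n = a.data.size

    def bwd(g):
        return ((np.broadcast_to(g, a.data.shape) / n).astype(np.float32),)

    return Tensor._node(a.data.mean(), (a,), bwd)


# -- shape ops ---------------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    orig = a.data.shape
    return Tensor._node(a.data.reshape(shape), (a,),
                        lambda g: (g.reshape(orig),))


def transpose(a: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)
    return Tensor._node(a.data.transpose(axes), (a,),
                        lambda g: (g.transpose(inv),))


def concat(tensors, axis: int) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._node(out, tuple(tensors), bwd)


# -- convolution -------------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, stride=(1, 1, 1), padding=(1, 1, 1)) -> Tensor:
    """3D cross-correlation on (batch, channel, height, width, depth).

    ``w`` has shape (out_ch, in_ch, kh, kw, kd).  Implemented as a sum of
    shifted GEMMs, one per kernel tap, so BLAS does the heavy lifting.
    """
    N, C, H, W, D = x.data.shape
    O, Ci, kh, kw, kd = w.data.shape
    if Ci != C:
        raise ValueError(f"conv3d channel mismatch: input {C}, weight {Ci}")
    sh, sw, sd = stride
    ph, pw, pd = padding
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1
    Do = (D + 2 * pd - kd) // sd + 1
    if min(Ho, Wo, Do) < 1:
        raise ValueError("conv3d: kernel larger than padded input")
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw), (pd, pd)))
    acc = np.zeros((O, N, Ho, Wo, Do), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            for k in range(kd):
                xs = xp[:, :, i:i + sh * Ho:sh, j:j + sw * Wo:sw,
                        k:k + sd * Do:sd]
                # (O,C) x (N,C,ho,wo,do) -> (O,N,ho,wo,do)
                acc += np.tensordot(w.data[:, :, i, j, k], xs,
                                    axes=([1], [1]))
    out = np.ascontiguousarray(acc.transpose(1, 0, 2, 3, 4))

    def bwd(g):
        gT = g.transpose(1, 0, 2, 3, 4)  # (O,N,ho,wo,do)
        dw = np.zeros_like(w.data)
        dxp = np.zeros_like(xp) if x.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                for k in range(kd):
                    sl = (slice(None), slice(None),
                          slice(i, i + sh * Ho, sh),
                          slice(j, j + sw * Wo, sw),
                          slice(k, k + sd * Do, sd))
                    xs = xp[sl]
                    if w.requires_grad:
                        # (O, N*ho*wo*do) x (N*.., C) -> (O, C)
                        dw[:, :, i, j, k] = np.tensordot(
                            gT, xs, axes=([1, 2, 3, 4], [0, 2, 3, 4]))
                    if dxp is not None:
                        # (C,O) x (O,N,ho,wo,do) -> (C,N,ho,wo,do)
                        dxs = np.tensordot(w.data[:, :, i, j, k].T, gT,
                                           axes=([1], [0]))
                        dxp[sl] += dxs.transpose(1, 0, 2, 3, 4)
        dx = None
        if dxp is not None:
            dx = dxp[:, :, ph:ph + H, pw:pw + W, pd:pd + D]
        return dx, dw

    return Tensor._node(out, (x, w), bwd)


def maxpool_hw(x: Tensor) -> Tensor:
    """2x2 max pool over the height/width axes of a 5-axis tensor."""
    N, C, H, W, D = x.data.shape
    Hh, Ww = H // 2, W // 2
    xr = x.data[:, :, :Hh * 2, :Ww * 2, :]
    win = xr.reshape(N, C, Hh, 2, Ww, 2, D).transpose(0, 1, 2, 4, 6, 3, 5)
    win = np.ascontiguousarray(win).reshape(N, C, Hh, Ww, D, 4)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    out = np.ascontiguousarray(out.transpose(0, 1, 2, 3, 4))

    def bwd(g):
        gwin = np.zeros((N, C, Hh, Ww, D, 4), dtype=np.float32)
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gr = gwin.reshape(N, C, Hh, Ww, D, 2, 2).transpose(0, 1, 2, 5, 3, 6, 4)
        gx = np.zeros_like(x.data)
        gx[:, :, :Hh * 2, :Ww * 2, :] = gr.reshape(N, C, Hh * 2, Ww * 2, D)
        return (gx,)

    return Tensor._node(out, (x,), bwd)


def depth_diff(x: Tensor) -> Tensor:
    """First difference along the trailing (depth) axis:
    out[..., d] = x[..., d+1] - x[..., d]."""
    out = x.data[..., 1:] - x.data[..., :-1]

    def bwd(g):
        gx = np.zeros_like(x.data)
        gx[..., 1:] += g
        gx[..., :-1] -= g
        return (gx,)

    return Tensor._node(out, (x,), bwd)


def upsample_depth_linear(x: Tensor, r: int) -> Tensor:
    """Trilinear (depth-only) upsampling by integer factor ``r``.

    Output depth index z maps to input coordinate (z - (r-1)/2) / r, the
    alignment induced by averaging groups of r consecutive slices; edges are
    clamped (nearest extension).
    """
    D = x.data.shape[-1]
    c = (np.arange(D * r, dtype=np.float64) - (r - 1) / 2.0) / r
    i0 = np.floor(c).astype(np.int64)
    w1 = (c - i0).astype(np.float32)
    i0c = np.clip(i0, 0, D - 1)
    i1c = np.clip(i0 + 1, 0, D - 1)
    w0 = 1.0 - w1
    out = x.data[..., i0c] * w0 + x.data[..., i1c] * w1

    def bwd(g):
        gx = np.zeros_like(x.data)
        gmoved = np.moveaxis(g, -1, 0)
        gxm = np.moveaxis(gx, -1, 0)
        np.add.at(gxm, i0c, gmoved * w0[(slice(None),) + (None,) * (g.ndim - 1)])
        np.add.at(gxm, i1c, gmoved * w1[(slice(None),) + (None,) * (g.ndim - 1)])
        return (gx,)

    return Tensor._node(out, (x,), bwd)
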