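"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operators the segmentation network needs are implemented:
same-padded k x k convolution (im2col), 2 x 2 stride-2 transposed
convolution, 2 x 2 max pooling, ReLU, sigmoid, channel-wise max/mean
reduction, channel concatenation, broadcast add/multiply, and a
numerically stable binary cross-entropy on logits.

All spatial tensors use NCHW layout.  Gradients are accumulated into
``Tensor.grad`` by :func:`backward`, which walks a topologically sorted
tape.  Wrapping a region in :func:`no_grad` skips tape construction
entirely (inference mode).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], tuple] | None = None
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad}, name={self.name!r})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    """Create a result tensor, attaching the backward closure only when
    gradients are enabled and some parent requires them."""
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad or p._backward is not None for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def backward(loss: Tensor) -> None:
    """Backpropagate d(loss)/d(x) into every reachable tensor's ``.grad``."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(loss, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen or node._backward is None and not node.requires_grad:
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    loss.grad = np.ones_like(loss.data)
    for node in reversed(topo):
        if node._backward is None or node.grad is None:
            continue
        grads = node._backward(node.grad)
        for parent, g in zip(node._parents, grads):
            if g is None:
                continue
            if parent.grad is None:
                parent.grad = g.astype(parent.data.dtype, copy=True)
            else:
                parent.grad += g


def _sum_to_shape(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------- arithmetic

def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def bwd(g):
        return _sum_to_shape(g, a.data.shape), _sum_to_shape(g, b.data.shape)

    return _make(data, (a, b), bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def bwd(g):
        return (_sum_to_shape(g * b.data, a.data.shape),
                _sum_to_shape(g * a.data, b.data.shape))

    return _make(data, (a, b), bwd)


def scale(a: Tensor, c: float) -> Tensor:
    data = a.data * c

    def bwd(g):
        return (g * c,)

    return _make(data, (a,), bwd)


# --------------------------------------------------------------- activations

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    data = np.where(mask, x.data, 0)

    def bwd(g):
        return (g * mask,)

    return _make(data, (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    # stable piecewise form
    z = x.data
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)

    def bwd(g):
        return (g * out * (1.0 - out),)

    return _make(out, (x,), bwd)


# ------------------------------------------------------------- shape plumbing

def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(data, tuple(tensors), bwd)


def channel_max(x: Tensor) -> Tensor:
    """Max over the channel axis of an NCHW tensor -> (N, 1, H, W)."""
    idx = x.data.argmax(axis=1, keepdims=True)
    data = np.take_along_axis(x.data, idx, axis=1)

    def bwd(g):
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, idx, g, axis=1)
        return (gx,)

    return _make(data, (x,), bwd)


def channel_mean(x: Tensor) -> Tensor:
    """Mean over the channel axis of an NCHW tensor -> (N, 1, H, W)."""
    c = x.data.shape[1]
    data = x.data.mean(axis=1, keepdims=True)

    def bwd(g):
        return (np.broadcast_to(g / c, x.data.shape).copy(),)

    return _make(data, (x,), bwd)


# --------------------------------------------------------------- convolution

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    cols = np.empty((n, c, k, k, h, w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + h, j:j + w]
    return cols


def _col2im(cols: np.ndarray, x_shape: tuple, k: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + h, j:j + w] += cols[:, :, i, j]
    return xp[:, :, pad:pad + h, pad:pad + w] if pad else xp


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded stride-1 convolution.

    ``x``: (N, Cin, H, W); ``w``: (Cout, Cin, k, k) with k odd; ``b``: (Cout,).
    Output: (N, Cout, H, W).  Zero padding of (k-1)/2 keeps the printed shape
    schedule exact.
    """
    n, cin, h, wd = x.data.shape
    cout, cin_w, k, k2 = w.data.shape
    assert k == k2 and k % 2 == 1 and cin == cin_w
    pad = (k - 1) // 2
    cols = _im2col(x.data, k, pad)                       # (N, Cin, k, k, H, W)
    cols2 = cols.reshape(n, cin * k * k, h * wd)
    wr = w.data.reshape(cout, cin * k * k)
    out = np.matmul(wr, cols2)                           # (N, Cout, H*W)
    out = out.reshape(n, cout, h, wd) + b.data[:, None, None]

    def bwd(g):
        g2 = g.reshape(n, cout, h * wd)
        gw = np.einsum("noh,nch->oc", g2, cols2, optimize=True).reshape(w.data.shape)
        gb = g.sum(axis=(0, 2, 3))
        gcols2 = np.matmul(wr.T, g2)                     # (N, Cin*k*k, H*W)
        gx = _col2im(gcols2.reshape(n, cin, k, k, h, wd), x.data.shape, k, pad)
        return gx, gw, gb

    return _make(out, (x, w, b), bwd)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2 x 2 stride-2 transposed convolution (exact spatial doubling).

    ``x``: (N, Cin, H, W); ``w``: (Cin, Cout, 2, 2); ``b``: (Cout,).
    Output: (N, Cout, 2H, 2W).
    """
    n, cin, h, wd = x.data.shape
    cin_w, cout, _, _ = w.data.shape
    assert cin == cin_w
    y6 = np.einsum("ncij,cdab->ndiajb", x.data, w.data, optimize=True)
    out = y6.reshape(n, cout, 2 * h, 2 * wd) + b.data[:, None, None]

    def bwd(g):
        g6 = g.reshape(n, cout, h, 2, wd, 2)
        gx = np.einsum("ndiajb,cdab->ncij", g6, w.data, optimize=True)
        gw = np.einsum("ncij,ndiajb->cdab", x.data, g6, optimize=True)
        gb = g.sum(axis=(0, 2, 3))
        return gx, gw, gb

    return _make(out, (x, w, b), bwd)


def upsample2x_nearest(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    data = x.data.repeat(2, axis=2).repeat(2, axis=3)
    n, c, h, w = x.data.shape

    def bwd(g):
        return (g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)),)

    return _make(data, (x,), bwd)


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    assert h % 2 == 0 and w % 2 == 0
    xr = (x.data.reshape(n, c, h // 2, 2, w // 2, 2)
          .transpose(0, 1, 2, 4, 3, 5)
          .reshape(n, c, h // 2, w // 2, 4))
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        gr = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = (gr.reshape(n, c, h // 2, w // 2, 2, 2)
              .transpose(0, 1, 2, 4, 3, 5)
              .reshape(n, c, h, w))
        return (gx,)

    return _make(out, (x,), bwd)


# --------------------------------------------------------------------- loss

def bce_with_logits(z: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed from logits (numerically stable).

    loss = mean( max(z,0) - z*y + log(1 + exp(-|z|)) )
    """
    y = np.asarray(target, dtype=z.data.dtype)
    zd = z.data
    loss = np.maximum(zd, 0) - zd * y + np.log1p(np.exp(-np.abs(zd)))
    data = np.asarray(loss.mean())
    inv_n = 1.0 / zd.size

    def bwd(g):
        p = np.empty_like(zd)
        pos = zd >= 0
        p[pos] = 1.0 / (1.0 + np.exp(-zd[pos]))
        ez = np.exp(zd[~pos])
        p[~pos] = ez / (1.0 + ez)
        return ((p - y) * (g * inv_n),)

    return _make(data, (z,), bwd)
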