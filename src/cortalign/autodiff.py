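"""Compact reverse-mode automatic differentiation over numpy arrays.

The registration network, the scaling-and-squaring integration and the
training objective are all expressed through the ops defined here; gradients
with respect to the convolution weights and the atlas channels flow through
bilinear resampling and the integration recursion.

Scope is deliberately narrow: exactly the tensor operations the model needs
(broadcast arithmetic, reductions, im2col convolution with wrap/edge padding,
2x2 max-pooling, nearest up-sampling, leaky rectifier, bilinear grid pull,
batch gather/concat).  Convolutions run as BLAS matrix products on im2col
buffers; the bilinear-pull adjoint scatters with ``bincount`` for speed.

Array layout is channels-last ``(batch, n_lat, n_lon, channels)``; longitude
(axis 2) wraps, latitude (axis 1) uses edge padding / clamped sampling,
matching :mod:`cortalign.interp`.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .interp import bilinear_corners

__all__ = ["Tensor", "tensor", "parameter", "concat", "grid_pull", "conv2d",
           "maxpool2", "upsample2", "leaky_relu", "take_batch", "expand_batch"]


class Tensor:
    """A node in the computation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bw")

    def __init__(self, data, requires_grad=False, parents=(), bw=None):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._bw = bw

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse-accumulate gradients from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if id(node) in seen:
                continue
            if expanded:
                seen.add(id(node))
                topo.append(node)
                continue
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._bw is not None and node.grad is not None:
                node._bw(node.grad)
            # free the tape reference once consumed
            node._bw = None
            node._parents = ()

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        return _binary(self, other, np.add, lambda g, a, b: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract, lambda g, a, b: (g, -g))

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda g, a, b: (g * b.data, g * a.data))

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise NotImplementedError("division only by constants")
        return self * (1.0 / other)

    def __neg__(self):
        return self * -1.0

    def sqr(self) -> "Tensor":
        return self * self

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape) -> "Tensor":
        src_shape = self.data.shape
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        if self.requires_grad:
            out._bw = lambda g: self._accum(g.reshape(src_shape))
        return out

    def __getitem__(self, key) -> "Tensor":
        out_data = self.data[key]
        out = Tensor(out_data, self.requires_grad, (self,))
        if self.requires_grad:
            def bw(g, key=key):
                gx = np.zeros_like(self.data)
                gx[key] += g
                self._accum(gx)
            out._bw = bw
        return out

    def roll(self, shift: int, axis: int) -> "Tensor":
        out = Tensor(np.roll(self.data, shift, axis=axis), self.requires_grad, (self,))
        if self.requires_grad:
            out._bw = lambda g: self._accum(np.roll(g, -shift, axis=axis))
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        out = Tensor(out_data, self.requires_grad, (self,))
        if self.requires_grad:
            def bw(g):
                if axis is None:
                    self._accum(np.broadcast_to(g, self.data.shape).copy())
                else:
                    ge = g if keepdims else np.expand_dims(g, axis)
                    self._accum(np.broadcast_to(ge, self.data.shape).copy())
            out._bw = bw
        return out

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(np.asarray(data), requires_grad=requires_grad)


def parameter(data) -> Tensor:
    """A leaf tensor that accumulates gradients (trainable)."""
    return Tensor(np.asarray(data), requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to `shape`."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _binary(a, b, fwd, grads) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    req = a.requires_grad or b.requires_grad
    out = Tensor(fwd(a.data, b.data), req, (a, b))
    if req:
        def bw(g):
            ga, gb = grads(g, a, b)
            if a.requires_grad:
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(gb, b.data.shape))
        out._bw = bw
    return out


# ---------------------------------------------------------------------- ops

def concat(tensors: list[Tensor], axis: int) -> Tensor:
    req = any(t.requires_grad for t in tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), req, tuple(tensors))
    if req:
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)
        def bw(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(g[tuple(sl)])
        out._bw = bw
    return out


def take_batch(t: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows along the batch axis (adjoint scatter-adds)."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(t.data[idx], t.requires_grad, (t,))
    if t.requires_grad:
        def bw(g):
            gx = np.zeros_like(t.data)
            np.add.at(gx, idx, g)
            t._accum(gx)
        out._bw = bw
    return out


def expand_batch(t: Tensor, n: int) -> Tensor:
    """Tile a (1, ...) tensor to batch size n; adjoint sums over the batch."""
    if t.data.shape[0] != 1:
        raise ValueError("expand_batch expects leading axis of size 1")
    out = Tensor(np.broadcast_to(t.data, (n, *t.data.shape[1:])).copy(),
                 t.requires_grad, (t,))
    if t.requires_grad:
        out._bw = lambda g: t._accum(g.sum(axis=0, keepdims=True))
    return out


def leaky_relu(t: Tensor, slope: float = 0.2) -> Tensor:
    mask = t.data >= 0
    out = Tensor(np.where(mask, t.data, slope * t.data), t.requires_grad, (t,))
    if t.requires_grad:
        out._bw = lambda g: t._accum(np.where(mask, g, slope * g))
    return out


_SCRATCH: dict[tuple, np.ndarray] = {}


def _scratch(tag: str, shape: tuple[int, ...], dtype) -> np.ndarray:
    """Reusable per-shape work buffer (training is single-threaded)."""
    key = (tag, shape, np.dtype(dtype).str)
    buf = _SCRATCH.get(key)
    if buf is None:
        buf = np.empty(shape, dtype=dtype)
        _SCRATCH[key] = buf
    return buf


def _pad_wrap_edge(x: np.ndarray, ph: int, pw: int, buf: np.ndarray) -> np.ndarray:
    """Pad into `buf`: wrap columns (longitude), replicate edge rows (latitude)."""
    _, hh, ww, _ = x.shape
    buf[:, ph:hh + ph, pw:ww + pw] = x
    if pw:
        buf[:, ph:hh + ph, :pw] = x[:, :, ww - pw:]
        buf[:, ph:hh + ph, ww + pw:] = x[:, :, :pw]
    for i in range(ph):
        buf[:, i] = buf[:, ph]
        buf[:, hh + ph + i] = buf[:, hh + ph - 1]
    return buf


def _im2col(xp: np.ndarray, kh: int, kw: int, out_h: int, out_w: int,
            buf: np.ndarray) -> np.ndarray:
    b, _, _, cin = xp.shape
    sb, sh, sw, sc = xp.strides
    view = as_strided(
        xp,
        shape=(b, out_h, out_w, kh, kw, cin),
        strides=(sb, sh, sw, sh, sw, sc),
        writeable=False,
    )
    np.copyto(buf, view)
    return buf.reshape(b * out_h * out_w, kh * kw * cin)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-size 2D convolution, wrap in longitude, edge-clamp in latitude.

    x: (B, H, W, Cin); w: (kh, kw, Cin, Cout); b: (Cout,).  Runs as a BLAS
    product on an im2col buffer; the buffer is scratch, recomputed in the
    backward pass rather than kept alive on the tape.
    """
    kh, kw, cin, cout = w.data.shape
    ph, pw = kh // 2, kw // 2
    bb, hh, ww, _ = x.data.shape
    dt = x.data.dtype
    pshape = (bb, hh + 2 * ph, ww + 2 * pw, cin)
    cshape = (bb, hh, ww, kh, kw, cin)
    xp = _pad_wrap_edge(x.data, ph, pw, _scratch("pad", pshape, dt))
    cols = _im2col(xp, kh, kw, hh, ww, _scratch("col", cshape, dt))
    wmat = w.data.reshape(kh * kw * cin, cout)
    out_data = (cols @ wmat + b.data).reshape(bb, hh, ww, cout)
    req = x.requires_grad or w.requires_grad or b.requires_grad
    out = Tensor(out_data, req, (x, w, b))
    if req:
        def bw(g):
            go = g.reshape(bb * hh * ww, cout)
            if b.requires_grad:
                b._accum(go.sum(axis=0))
            if w.requires_grad:
                xp2 = _pad_wrap_edge(x.data, ph, pw, _scratch("pad", pshape, dt))
                cols2 = _im2col(xp2, kh, kw, hh, ww, _scratch("col", cshape, dt))
                w._accum((cols2.T @ go).reshape(kh, kw, cin, cout))
            if x.requires_grad:
                gcols = np.matmul(
                    go, wmat.T, out=_scratch("gcol", cshape, dt).reshape(
                        bb * hh * ww, kh * kw * cin)
                ).reshape(cshape)
                gxp = _scratch("gpad", pshape, dt)
                gxp.fill(0)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, i:i + hh, j:j + ww, :] += gcols[:, :, :, i, j, :]
                # adjoint of edge padding in latitude
                gwp = gxp[:, ph:hh + ph]
                if ph:
                    gwp[:, 0] += gxp[:, :ph].sum(axis=1)
                    gwp[:, -1] += gxp[:, hh + ph:].sum(axis=1)
                # adjoint of wrap padding in longitude
                gx = gwp[:, :, pw:ww + pw].copy()
                if pw:
                    gx[:, :, ww - pw:] += gwp[:, :, :pw]
                    gx[:, :, :pw] += gwp[:, :, ww + pw:]
                x._accum(gx)
        out._bw = bw
    return out


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling (both spatial dims must be even)."""
    bb, hh, ww, cc = x.data.shape
    h2, w2 = hh // 2, ww // 2
    blocks = (
        x.data.reshape(bb, h2, 2, w2, 2, cc)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(bb, h2, w2, 4, cc)
    )
    idx = blocks.argmax(axis=3)
    out_data = np.take_along_axis(blocks, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    out = Tensor(out_data, x.requires_grad, (x,))
    if x.requires_grad:
        def bw(g):
            g4 = np.zeros_like(blocks)
            np.put_along_axis(g4, idx[:, :, :, None, :], g[:, :, :, None, :], axis=3)
            gx = (
                g4.reshape(bb, h2, w2, 2, 2, cc)
                .transpose(0, 1, 3, 2, 4, 5)
                .reshape(bb, hh, ww, cc)
            )
            x._accum(gx)
        out._bw = bw
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbor 2x up-sampling of both spatial dims."""
    out_data = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)
    out = Tensor(out_data, x.requires_grad, (x,))
    if x.requires_grad:
        bb, hh, ww, cc = x.data.shape
        def bw(g):
            x._accum(g.reshape(bb, hh, 2, ww, 2, cc).sum(axis=(2, 4)))
        out._bw = bw
    return out


def disp_pull(x: Tensor, u: Tensor) -> Tensor:
    """Bilinear pull-back through phi = Id + u (fused, kernel-backed).

    ``out[b,i,j] = x[b](i + u[b,i,j,0], j + u[b,i,j,1])`` with longitude
    wrap and latitude clamp; differentiable in both the image and the
    displacement.
    """
    from ._kernels import pull_disp_bwd, pull_disp_fwd

    if x.data.shape[:3] != u.data.shape[:3] or u.data.shape[-1] != 2:
        raise ValueError("displacement must be (B, H, W, 2) matching the image")
    out_data = pull_disp_fwd(x.data, u.data)
    req = x.requires_grad or u.requires_grad
    out = Tensor(out_data, req, (x, u))
    if req:
        def bw(g):
            gx, gu = pull_disp_bwd(x.data, u.data, np.ascontiguousarray(g),
                                   x.requires_grad, u.requires_grad)
            if gx is not None:
                x._accum(gx)
            if gu is not None:
                u._accum(gu)
        out._bw = bw
    return out


def grid_pull(x: Tensor, coords: Tensor) -> Tensor:
    """Bilinear sampling: out[b, i, j] = x[b] evaluated at coords[b, i, j].

    ``coords[..., 0]`` are absolute row coordinates (clamped at the latitude
    boundary), ``coords[..., 1]`` absolute columns (wrapped).  Differentiable
    in both the image and the sampling coordinates.
    """
    bb, hh, ww, cc = x.data.shape
    r = coords.data[..., 0]
    c = coords.data[..., 1]
    r0, r1, c0, c1, fr, fc, r_ok = bilinear_corners(r, c, hh, ww)
    b_idx = np.arange(bb, dtype=np.intp)[:, None, None]
    v00 = x.data[b_idx, r0, c0]
    v01 = x.data[b_idx, r0, c1]
    v10 = x.data[b_idx, r1, c0]
    v11 = x.data[b_idx, r1, c1]
    w00 = (1 - fr) * (1 - fc)
    w01 = (1 - fr) * fc
    w10 = fr * (1 - fc)
    w11 = fr * fc
    out_data = (
        w00[..., None] * v00 + w01[..., None] * v01
        + w10[..., None] * v10 + w11[..., None] * v11
    )
    req = x.requires_grad or coords.requires_grad
    out = Tensor(out_data, req, (x, coords))
    if req:
        flat00 = ((b_idx * hh + r0) * ww + c0).ravel()
        flat01 = ((b_idx * hh + r0) * ww + c1).ravel()
        flat10 = ((b_idx * hh + r1) * ww + c0).ravel()
        flat11 = ((b_idx * hh + r1) * ww + c1).ravel()
        def bw(g):
            if x.requires_grad:
                gx = np.zeros((bb * hh * ww, cc), dtype=x.data.dtype)
                for flat, wgt in ((flat00, w00), (flat01, w01), (flat10, w10), (flat11, w11)):
                    contrib = wgt[..., None] * g
                    for ch in range(cc):
                        gx[:, ch] += np.bincount(
                            flat, weights=contrib[..., ch].ravel(), minlength=bb * hh * ww
                        )
                x._accum(gx.reshape(bb, hh, ww, cc).astype(x.data.dtype, copy=False))
            if coords.requires_grad:
                dvdr = (1 - fc)[..., None] * (v10 - v00) + fc[..., None] * (v11 - v01)
                dvdc = (1 - fr)[..., None] * (v01 - v00) + fr[..., None] * (v11 - v10)
                gr = (g * dvdr).sum(axis=-1) * r_ok  # clamped rows: zero slope
                gc = (g * dvdc).sum(axis=-1)
                coords._accum(np.stack([gr, gc], axis=-1).astype(coords.data.dtype, copy=False))
        out._bw = bw
    return out
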