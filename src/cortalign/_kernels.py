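"""Low-level fused kernels for bilinear displacement sampling.

Numba-compiled loops implementing the forward and adjoint of
``out[b,i,j] = x[b](i + u[b,i,j,0], j + u[b,i,j,1])`` with longitude wrap
and latitude clamp (the convention of :mod:`cortalign.interp`).  A pure
numpy fallback keeps the package importable without a working JIT.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn
        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=True)
def _pull_disp_fwd(x, u, out):
    b_n, h, w, c = x.shape
    for b in range(b_n):
        for i in range(h):
            for j in range(w):
                rr = i + u[b, i, j, 0]
                if rr < 0.0:
                    rr = 0.0
                elif rr > h - 1.0:
                    rr = h - 1.0
                r0 = int(rr)
                if r0 > h - 2:
                    r0 = h - 2
                fr = rr - r0
                cc = j + u[b, i, j, 1]
                cc = cc - math.floor(cc / w) * w
                c0 = int(cc)
                fc = cc - c0
                if c0 >= w:
                    c0 -= w
                    fc = 0.0
                c1 = c0 + 1
                if c1 >= w:
                    c1 -= w
                w00 = (1.0 - fr) * (1.0 - fc)
                w01 = (1.0 - fr) * fc
                w10 = fr * (1.0 - fc)
                w11 = fr * fc
                for ch in range(c):
                    out[b, i, j, ch] = (
                        w00 * x[b, r0, c0, ch] + w01 * x[b, r0, c1, ch]
                        + w10 * x[b, r0 + 1, c0, ch] + w11 * x[b, r0 + 1, c1, ch]
                    )


@njit(cache=True, fastmath=True)
def _pull_disp_bwd(x, u, go, gx, gu, need_gx, need_gu):
    b_n, h, w, c = x.shape
    for b in range(b_n):
        for i in range(h):
            for j in range(w):
                rr_raw = i + u[b, i, j, 0]
                r_ok = 0.0 <= rr_raw <= h - 1.0
                rr = rr_raw
                if rr < 0.0:
                    rr = 0.0
                elif rr > h - 1.0:
                    rr = h - 1.0
                r0 = int(rr)
                if r0 > h - 2:
                    r0 = h - 2
                fr = rr - r0
                cc = j + u[b, i, j, 1]
                cc = cc - math.floor(cc / w) * w
                c0 = int(cc)
                fc = cc - c0
                if c0 >= w:
                    c0 -= w
                    fc = 0.0
                c1 = c0 + 1
                if c1 >= w:
                    c1 -= w
                w00 = (1.0 - fr) * (1.0 - fc)
                w01 = (1.0 - fr) * fc
                w10 = fr * (1.0 - fc)
                w11 = fr * fc
                gr = 0.0
                gc = 0.0
                for ch in range(c):
                    g = go[b, i, j, ch]
                    if need_gx:
                        gx[b, r0, c0, ch] += w00 * g
                        gx[b, r0, c1, ch] += w01 * g
                        gx[b, r0 + 1, c0, ch] += w10 * g
                        gx[b, r0 + 1, c1, ch] += w11 * g
                    if need_gu:
                        v00 = x[b, r0, c0, ch]
                        v01 = x[b, r0, c1, ch]
                        v10 = x[b, r0 + 1, c0, ch]
                        v11 = x[b, r0 + 1, c1, ch]
                        gr += g * ((1.0 - fc) * (v10 - v00) + fc * (v11 - v01))
                        gc += g * ((1.0 - fr) * (v01 - v00) + fr * (v11 - v10))
                if need_gu:
                    gu[b, i, j, 0] = gr if r_ok else 0.0
                    gu[b, i, j, 1] = gc


def pull_disp_fwd(x: np.ndarray, u: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    if HAVE_NUMBA:
        _pull_disp_fwd(x, u, out)
        return out
    from .interp import sample_channels  # numpy fallback

    b_n, h, w, _ = x.shape
    rr, cc = np.meshgrid(np.arange(h, dtype=x.dtype), np.arange(w, dtype=x.dtype),
                         indexing="ij")
    for b in range(b_n):
        sampled = sample_channels(np.moveaxis(x[b], -1, 0),
                                  rr + u[b, ..., 0], cc + u[b, ..., 1])
        out[b] = np.moveaxis(sampled, 0, -1)
    return out


def pull_disp_bwd(x: np.ndarray, u: np.ndarray, go: np.ndarray,
                  need_gx: bool, need_gu: bool):
    gx = np.zeros_like(x) if need_gx else np.zeros((1, 1, 1, 1), dtype=x.dtype)
    gu = np.empty_like(u) if need_gu else np.zeros((1, 1, 1, 2), dtype=u.dtype)
    if HAVE_NUMBA:
        _pull_disp_bwd(x, u, go, gx, gu, need_gx, need_gu)
        return (gx if need_gx else None), (gu if need_gu else None)
    # numpy fallback mirrors the corner conventions of interp.bilinear_corners
    from .interp import bilinear_corners

    b_n, h, w, c = x.shape
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                         indexing="ij")
    r = rr[None] + u[..., 0]
    col = cc[None] + u[..., 1]
    r0, r1, c0, c1, fr, fc, r_ok = bilinear_corners(r, col, h, w)
    b_idx = np.arange(b_n, dtype=np.intp)[:, None, None]
    ws = ((1 - fr) * (1 - fc), (1 - fr) * fc, fr * (1 - fc), fr * fc)
    corners = ((r0, c0), (r0, c1), (r1, c0), (r1, c1))
    if need_gx:
        flatsize = b_n * h * w
        gx_flat = gx.reshape(flatsize, c)
        for (ri, ci), wgt in zip(corners, ws):
            flat = ((b_idx * h + ri) * w + ci).ravel()
            contrib = wgt[..., None] * go
            for ch in range(c):
                gx_flat[:, ch] += np.bincount(flat, weights=contrib[..., ch].ravel(),
                                              minlength=flatsize)
    if need_gu:
        v = [x[b_idx, ri, ci] for ri, ci in corners]
        dvdr = (1 - fc)[..., None] * (v[2] - v[0]) + fc[..., None] * (v[3] - v[1])
        dvdc = (1 - fr)[..., None] * (v[1] - v[0]) + fr[..., None] * (v[3] - v[2])
        gu[..., 0] = (go * dvdr).sum(axis=-1) * r_ok
        gu[..., 1] = (go * dvdc).sum(axis=-1)
    return (gx if need_gx else None), (gu if need_gu else None)
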