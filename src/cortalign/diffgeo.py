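"""Differentiable (batched) counterparts of the deformation algebra.

Tensor layout is ``(batch, n_lat, n_lon, comp/channel)`` with displacement
component 0 along latitude and 1 along longitude, mirroring the
``(2, n_lat, n_lon)`` numpy layout in :mod:`cortalign.deformation`.  Both
paths share the corner/seam conventions of :mod:`cortalign.interp`.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, disp_pull

__all__ = ["base_coords", "integrate", "compose_disp", "warp_channels",
           "to_batch_disp", "from_batch_disp"]

_BASE_CACHE: dict[tuple[int, int], np.ndarray] = {}


def base_coords(n_lat: int, n_lon: int) -> np.ndarray:
    """Identity sampling coordinates, shape (1, n_lat, n_lon, 2)."""
    key = (n_lat, n_lon)
    if key not in _BASE_CACHE:
        rr, cc = np.meshgrid(
            np.arange(n_lat, dtype=float), np.arange(n_lon, dtype=float), indexing="ij"
        )
        _BASE_CACHE[key] = np.stack([rr, cc], axis=-1)[None]
    return _BASE_CACHE[key]


def integrate(v: Tensor, n_steps: int = 7) -> Tensor:
    """Scaling-and-squaring exponential of a batched velocity (B,H,W,2)."""
    u = v * float(2.0 ** -n_steps)
    for _ in range(n_steps):
        u = u + disp_pull(u, u)
    return u


def compose_disp(u_outer: Tensor, u_inner: Tensor) -> Tensor:
    """Displacement of phi_outer o phi_inner (both (B,H,W,2))."""
    return u_inner + disp_pull(u_outer, u_inner)


def warp_channels(img: Tensor, u: Tensor) -> Tensor:
    """Pull back image channels (B,H,W,C) through phi = Id + u."""
    return disp_pull(img, u)


def to_batch_disp(u: np.ndarray) -> np.ndarray:
    """(2, H, W) -> (1, H, W, 2)."""
    return np.moveaxis(u, 0, -1)[None]


def from_batch_disp(u: np.ndarray) -> np.ndarray:
    """(B, H, W, 2) -> (2, H, W) for batch size 1."""
    return np.moveaxis(u[0], -1, 0)
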