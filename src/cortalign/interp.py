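"""Bilinear sampling on the parameterized grid.

Single seam convention used everywhere in the package: the longitude axis
(columns) wraps periodically, the latitude axis (rows) clamps at the first
and last row (no cross-pole wrap).  Both the plain-numpy deformation algebra
and the differentiable training path resolve sampling through the corner
computation here, so they cannot drift apart numerically.
"""

from __future__ import annotations

import numpy as np

__all__ = ["bilinear_corners", "sample_channels"]


def bilinear_corners(r: np.ndarray, c: np.ndarray, n_lat: int, n_lon: int):
    """Corner indices and weights for bilinear sampling at (r, c).

    Returns ``(r0, r1, c0, c1, fr, fc, r_in_range)`` where ``fr``/``fc`` are
    the fractional offsets and ``r_in_range`` flags rows whose latitude
    coordinate did not need clamping (the sampled value is constant, hence
    has zero derivative, in the clamped region).
    """
    r = np.asarray(r, dtype=float)
    c = np.asarray(c, dtype=float)
    r_in_range = (r >= 0.0) & (r <= n_lat - 1.0)
    rc = np.clip(r, 0.0, n_lat - 1.0)
    r0 = np.minimum(np.floor(rc), n_lat - 2).astype(np.intp) if n_lat > 1 else np.zeros_like(rc, dtype=np.intp)
    r1 = r0 + 1
    fr = rc - r0

    cw = np.mod(c, n_lon)
    c0 = np.floor(cw).astype(np.intp) % n_lon
    c1 = (c0 + 1) % n_lon
    fc = cw - np.floor(cw)
    return r0, r1, c0, c1, fr, fc, r_in_range


def sample_channels(values: np.ndarray, r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Sample ``values`` of shape (..., n_lat, n_lon) at fractional (r, c).

    ``r`` and ``c`` share an arbitrary common shape S; the result has shape
    ``values.shape[:-2] + S``.  Longitude wraps, latitude clamps.
    """
    n_lat, n_lon = values.shape[-2:]
    r0, r1, c0, c1, fr, fc, _ = bilinear_corners(r, c, n_lat, n_lon)
    v00 = values[..., r0, c0]
    v01 = values[..., r0, c1]
    v10 = values[..., r1, c0]
    v11 = values[..., r1, c1]
    return (
        (1.0 - fr) * (1.0 - fc) * v00
        + (1.0 - fr) * fc * v01
        + fr * (1.0 - fc) * v10
        + fr * fc * v11
    )
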