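"""Stationary-velocity-field diffeomorphism algebra on the lat-long grid.

A deformation is represented by its displacement ``u`` in grid-cell units,
``phi = Id + u``, with component 0 along the latitude (row) axis and
component 1 along the periodic longitude (column) axis.  Diffeomorphisms are
obtained as flows of stationary velocity fields via scaling-and-squaring;
their inverses as the flow of the negated velocity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import FeatureMap, SphericalGrid
from .interp import sample_channels

__all__ = [
    "VelocityField",
    "DeformationField",
    "integrate_svf",
    "compose",
    "warp",
    "warp_array",
    "jacobian_determinant",
    "negative_jacobian_fraction",
    "invert",
    "DEFAULT_INT_STEPS",
]

#: default scaling-and-squaring depth
DEFAULT_INT_STEPS = 7


@dataclass
class VelocityField:
    """Stationary velocity on the grid, shape (2, n_lat, n_lon), cell units."""

    grid: SphericalGrid
    v: np.ndarray

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.v.shape != (2, *self.grid.shape):
            raise ValueError(f"velocity must be (2, {self.grid.n_lat}, {self.grid.n_lon})")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("velocity must be finite")

    def __neg__(self) -> "VelocityField":
        return VelocityField(self.grid, -self.v)


@dataclass
class DeformationField:
    """Dense map phi = Id + u with displacement u in grid-cell units."""

    grid: SphericalGrid
    u: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.shape != (2, *self.grid.shape):
            raise ValueError(f"displacement must be (2, {self.grid.n_lat}, {self.grid.n_lon})")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement must be finite")

    @classmethod
    def identity(cls, grid: SphericalGrid) -> "DeformationField":
        return cls(grid, np.zeros((2, *grid.shape)))

    def mapped_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Absolute target coordinates (rows, cols) of phi at every cell."""
        rr, cc = np.meshgrid(
            np.arange(self.grid.n_lat, dtype=float),
            np.arange(self.grid.n_lon, dtype=float),
            indexing="ij",
        )
        return rr + self.u[0], cc + self.u[1]


def integrate_svf(v: VelocityField, n_steps: int = DEFAULT_INT_STEPS) -> DeformationField:
    """Exponentiate a stationary velocity field by scaling and squaring.

    The velocity is scaled by 2**-n_steps and the resulting small
    displacement self-composed ``n_steps`` times, approximating the flow
    exp(v) of the stationary ODE dx/dt = v(x).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not np.any(v.v):  # exp(0) = Id, exactly
        return DeformationField(v.grid, np.zeros_like(v.v))
    u = v.v / float(2**n_steps)
    for _ in range(n_steps):
        u = _compose_disp(u, u)
    return DeformationField(v.grid, u)


def _compose_disp(u_outer: np.ndarray, u_inner: np.ndarray) -> np.ndarray:
    """Displacement of phi_outer o phi_inner given both displacements."""
    n_lat, n_lon = u_outer.shape[1:]
    rr, cc = np.meshgrid(
        np.arange(n_lat, dtype=float), np.arange(n_lon, dtype=float), indexing="ij"
    )
    sampled = sample_channels(u_outer, rr + u_inner[0], cc + u_inner[1])
    return u_inner + sampled


def compose(phi_outer: DeformationField, phi_inner: DeformationField) -> DeformationField:
    """(phi_outer o phi_inner)(x) = phi_outer(phi_inner(x))."""
    if phi_outer.grid != phi_inner.grid:
        raise ValueError("deformations must share a grid")
    return DeformationField(phi_outer.grid, _compose_disp(phi_outer.u, phi_inner.u))


def warp_array(values: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Pull back channel data: out(x) = values(x + u(x)), bilinear."""
    n_lat, n_lon = values.shape[-2:]
    rr, cc = np.meshgrid(
        np.arange(n_lat, dtype=float), np.arange(n_lon, dtype=float), indexing="ij"
    )
    return sample_channels(values, rr + u[0], cc + u[1])


def warp(fm: FeatureMap, phi: DeformationField) -> FeatureMap:
    """Resample a feature map through a deformation, out(x) = fm(phi(x))."""
    if fm.grid != phi.grid:
        raise ValueError("feature map and deformation must share a grid")
    out = warp_array(fm.values, phi.u)
    return FeatureMap(fm.grid, out, fm.channel_roles, fm.valid_mask.copy())


def jacobian_determinant(phi: DeformationField) -> np.ndarray:
    """Determinant of the central-difference Jacobian of x -> x + u(x).

    Longitude derivatives use periodic central differences on the
    displacement (adding the identity gradient analytically, which avoids the
    2*pi seam jump); latitude derivatives are central in the interior and
    one-sided on the first/last row.  Identity gives det = 1 everywhere.
    """
    u = phi.u

    def d_dr(a: np.ndarray) -> np.ndarray:
        out = np.empty_like(a)
        out[1:-1] = (a[2:] - a[:-2]) / 2.0
        out[0] = a[1] - a[0]
        out[-1] = a[-1] - a[-2]
        return out

    def d_dc(a: np.ndarray) -> np.ndarray:
        return (np.roll(a, -1, axis=1) - np.roll(a, 1, axis=1)) / 2.0

    j00 = 1.0 + d_dr(u[0])  # d(row-map)/d(row)
    j01 = d_dc(u[0])
    j10 = d_dr(u[1])
    j11 = 1.0 + d_dc(u[1])
    return j00 * j11 - j01 * j10


def negative_jacobian_fraction(phi: DeformationField) -> float:
    """Percentage of grid locations where the map folds (det <= 0)."""
    det = jacobian_determinant(phi)
    return 100.0 * float(np.count_nonzero(det <= 0.0)) / det.size


def invert(v: VelocityField, n_steps: int = DEFAULT_INT_STEPS) -> DeformationField:
    """Flow of the negated velocity: the group inverse of integrate_svf(v)."""
    return integrate_svf(-v, n_steps)
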