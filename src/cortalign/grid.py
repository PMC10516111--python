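"""Latitude-longitude parameterization of spherical cortical data.

Cortical surfaces are assumed already inflated to the unit sphere and rigidly
aligned; this module maps per-vertex features onto a cell-centered 2D
latitude-longitude grid, provides the sin(theta) area-distortion weights used
throughout the losses and evaluation metrics, and standardizes feature
channels (median subtraction, standard-deviation division).

Conventions
-----------
* Rows index elevation theta in (0, pi); columns index azimuth phi in
  [0, 2*pi), periodic.  Cell centers exclude the exact poles so that
  sin(theta) > 0 on every row.
* Feature arrays are ``(channels, n_lat, n_lon)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "SphericalGrid",
    "FeatureMap",
    "WeightMap",
    "make_grid",
    "distortion_weights",
    "parameterize",
    "standardize",
    "GEOMETRIC",
    "FUNCTIONAL",
]

GEOMETRIC = "geometric"
FUNCTIONAL = "functional"

#: floor on the per-channel standard deviation; keeps constant channels finite
SD_FLOOR = 1e-6

MIN_GRID_DIM = 4


@dataclass(frozen=True)
class SphericalGrid:
    """Cell-centered latitude-longitude sampling grid on the unit sphere."""

    n_lat: int
    n_lon: int
    theta: np.ndarray  # (n_lat,) elevation, strictly inside (0, pi)
    phi: np.ndarray  # (n_lon,) azimuth in [0, 2*pi), uniform, periodic

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        phi = np.asarray(self.phi, dtype=float)
        if theta.shape != (self.n_lat,) or phi.shape != (self.n_lon,):
            raise ValueError("theta/phi lengths must match n_lat/n_lon")
        if not (np.all(np.diff(theta) > 0) and theta[0] > 0 and theta[-1] < np.pi):
            raise ValueError("theta must be strictly increasing inside (0, pi)")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "phi", phi)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SphericalGrid):
            return NotImplemented
        return (
            self.n_lat == other.n_lat
            and self.n_lon == other.n_lon
            and np.allclose(self.theta, other.theta)
            and np.allclose(self.phi, other.phi)
        )


@dataclass
class FeatureMap:
    """Multi-channel feature values on a :class:`SphericalGrid`.

    Parameters
    ----------
    grid
        The sampling grid.
    values
        Array of shape ``(n_channels, n_lat, n_lon)``.
    channel_roles
        One of ``"geometric"`` / ``"functional"`` per channel; at least one
        geometric channel must be present.
    valid_mask
        Per-channel presence flags; functional channels may be marked absent
        (semi-supervised training).  Defaults to all-present.
    """

    grid: SphericalGrid
    values: np.ndarray
    channel_roles: tuple[str, ...]
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1:] != self.grid.shape:
            raise ValueError(
                f"values must be (channels, {self.grid.n_lat}, {self.grid.n_lon})"
            )
        self.channel_roles = tuple(self.channel_roles)
        if len(self.channel_roles) != self.values.shape[0]:
            raise ValueError("one role per channel required")
        bad = set(self.channel_roles) - {GEOMETRIC, FUNCTIONAL}
        if bad:
            raise ValueError(f"unknown channel roles: {bad}")
        if GEOMETRIC not in self.channel_roles:
            raise ValueError("at least one geometric channel is required")
        if self.valid_mask is None:
            self.valid_mask = np.ones(len(self.channel_roles), dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != (len(self.channel_roles),):
                raise ValueError("valid_mask must have one flag per channel")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("values must be finite on valid channels")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def channels_with_role(self, role: str) -> np.ndarray:
        """Indices of channels carrying `role`."""
        return np.array([i for i, r in enumerate(self.channel_roles) if r == role])

    def select(self, role: str) -> "FeatureMap":
        """A FeatureMap restricted to channels of a single role.

        Selecting functional channels alone still requires a geometric anchor,
        so the restriction is only exposed for internal array use via
        :meth:`role_values`; this method keeps geometric channels.
        """
        idx = self.channels_with_role(role)
        if role != GEOMETRIC:
            raise ValueError("select() only supports the geometric role")
        return FeatureMap(
            self.grid,
            self.values[idx],
            tuple(self.channel_roles[i] for i in idx),
            self.valid_mask[idx],
        )

    def role_values(self, role: str) -> np.ndarray:
        """Raw value array for channels of the given role."""
        return self.values[self.channels_with_role(role)]

    def copy(self) -> "FeatureMap":
        return FeatureMap(
            self.grid, self.values.copy(), self.channel_roles, self.valid_mask.copy()
        )


@dataclass(frozen=True)
class WeightMap:
    """Row-constant sin(theta) area-distortion weights, max-normalized to 1."""

    grid: SphericalGrid
    w: np.ndarray  # (n_lat, n_lon), nonnegative

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.shape != self.grid.shape:
            raise ValueError("weight shape must match grid")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        object.__setattr__(self, "w", w)


def make_grid(n_lat: int, n_lon: int) -> SphericalGrid:
    """Build a cell-centered grid: theta_i = pi*(i+1/2)/n_lat, phi_j = 2*pi*j/n_lon.

    Cell-centering keeps the exact poles out of the grid, so sin(theta) never
    vanishes and the distortion weights stay strictly positive.
    """
    if n_lat < MIN_GRID_DIM or n_lon < MIN_GRID_DIM:
        raise ValueError(f"grid must be at least {MIN_GRID_DIM}x{MIN_GRID_DIM}")
    theta = np.pi * (np.arange(n_lat) + 0.5) / n_lat
    phi = 2.0 * np.pi * np.arange(n_lon) / n_lon
    return SphericalGrid(n_lat=int(n_lat), n_lon=int(n_lon), theta=theta, phi=phi)


def distortion_weights(grid: SphericalGrid) -> WeightMap:
    """sin(theta) area weights, constant along rows, normalized to max 1.

    The lat-long parameterization oversamples high latitudes; weighting each
    cell proportionally to sin(theta) restores (up to a constant) the true
    spherical area measure in every spatial average.
    """
    s = np.sin(grid.theta)
    w_row = s / s.max()
    w = np.repeat(w_row[:, None], grid.n_lon, axis=1)
    return WeightMap(grid=grid, w=w)


def _unit_vectors(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Cartesian unit vectors for paired (theta, phi) angles, shape (..., 3)."""
    st = np.sin(theta)
    return np.stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)], axis=-1)


def parameterize(
    vertex_coords: np.ndarray,
    vertex_values: np.ndarray,
    grid: SphericalGrid,
    channel_roles: tuple[str, ...] | None = None,
    k: int = 3,
) -> FeatureMap:
    """Resample per-vertex spherical data onto the lat-long grid.

    Each grid cell takes an inverse-great-circle-distance weighted average of
    its `k` nearest vertices; an exact hit takes the vertex value.  The
    longitude seam is handled automatically because neighbor search runs in
    3D Cartesian space.

    Parameters
    ----------
    vertex_coords : (n_vertices, 3), within 1e-3 of unit norm.
    vertex_values : (n_vertices,) or (n_vertices, n_channels).
    """
    coords = np.asarray(vertex_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
        raise ValueError("vertex_coords must be a nonempty (n, 3) array")
    norms = np.linalg.norm(coords, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-3):
        raise ValueError("vertex coordinates must lie on the unit sphere (tol 1e-3)")
    values = np.asarray(vertex_values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if values.shape[0] != coords.shape[0]:
        raise ValueError("one value row per vertex required")
    n_ch = values.shape[1]
    if channel_roles is None:
        channel_roles = (GEOMETRIC,) * n_ch

    coords = coords / norms[:, None]
    k_eff = min(k, coords.shape[0])
    tree = cKDTree(coords)

    tg, pg = np.meshgrid(grid.theta, grid.phi, indexing="ij")
    cell_xyz = _unit_vectors(tg.ravel(), pg.ravel())
    _, idx = tree.query(cell_xyz, k=k_eff)
    idx = np.atleast_2d(idx.reshape(cell_xyz.shape[0], k_eff))

    # great-circle distance to each neighbor
    dots = np.einsum("qd,qkd->qk", cell_xyz, coords[idx])
    arc = np.arccos(np.clip(dots, -1.0, 1.0))

    exact = arc < 1e-12
    inv = np.where(exact, 0.0, 1.0 / np.maximum(arc, 1e-12))
    has_exact = exact.any(axis=1)
    inv[has_exact] = exact[has_exact].astype(float)
    weights = inv / inv.sum(axis=1, keepdims=True)

    interp = np.einsum("qk,qkc->qc", weights, values[idx])
    out = interp.T.reshape(n_ch, grid.n_lat, grid.n_lon)
    return FeatureMap(grid=grid, values=out, channel_roles=channel_roles)


def standardize(fm: FeatureMap) -> FeatureMap:
    """Per-channel standardization: subtract the median, divide by the sd.

    Applied independently per channel (hence identically in form but
    separately for geometric and functional roles).  A floor of ``SD_FLOOR``
    on the standard deviation maps constant channels to all-zeros instead of
    dividing by zero.  Channels flagged absent are passed through untouched.
    """
    out = fm.values.copy()
    for c in range(fm.n_channels):
        if not fm.valid_mask[c]:
            continue
        ch = fm.values[c]
        med = np.median(ch)
        sd = ch.std()
        out[c] = (ch - med) / max(sd, SD_FLOOR)
    return replace(fm.copy(), values=out)
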