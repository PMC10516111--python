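"""Forward simulator of the generative model behind the registration objective.

A cohort is produced by (i) building a known multi-channel atlas - a banded
sinusoidal folding pattern for the geometric channel and smooth positive
activation blobs, longitudinally offset from the folds, for the functional
channel; (ii) warping it per subject by a large joint diffeomorphism
exp(v_j) into a latent joint image; (iii) further warping the geometric and
functional channels by small per-modality diffeomorphisms exp(v_g), exp(v_f);
with additive Gaussian noise at both stages.  Ground-truth velocities and
noise realizations are retained so that registration recovery can be scored
exactly.

Velocities are sampled as Gaussian white noise smoothed to a configurable
length scale and rescaled so the peak speed equals the configured amplitude,
which keeps every simulated deformation diffeomorphic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .deformation import DeformationField, VelocityField, integrate_svf, warp_array
from .grid import FUNCTIONAL, GEOMETRIC, FeatureMap, SphericalGrid, make_grid

__all__ = ["GenerativeConfig", "SyntheticSubject", "SyntheticCohort",
           "make_true_atlas", "sample_subject", "make_cohort",
           "sample_smooth_velocity"]


@dataclass(frozen=True)
class GenerativeConfig:
    """Study conditions for the reference synthetic cohorts.

    Amplitudes are peak speeds in grid cells: the joint (between-subject)
    deformation is large, the per-modality ones small, reflecting the model
    premise that within-subject geometry-function discrepancies are modest
    relative to between-subject variability.  ``sigma_noise`` is the additive
    noise sd of *each* of the two observation stages, so the marginal
    variance of an observed channel around the warped atlas is 2 sigma^2.
    ``func_offset`` shifts the functional blobs away from the geometric
    ridges (in cells, longitudinally), making the optimal functional
    alignment genuinely different from the geometric one.
    """

    n_lat: int = 64
    n_lon: int = 128
    n_subjects: int = 20
    joint_amplitude: float = 3.0
    modality_amplitude: float = 0.8
    smoothness_scale: float = 6.0
    sigma_noise: float = 0.25
    func_offset: float = 5.0
    n_blobs: int = 6
    blob_width: float = 4.0
    func_fraction: float = 1.0
    centered: bool = True
    int_steps: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.joint_amplitude < 0 or self.modality_amplitude < 0:
            raise ValueError("amplitudes must be nonnegative")
        if self.joint_amplitude > 0 and not self.modality_amplitude < self.joint_amplitude:
            raise ValueError("modality_amplitude must be smaller than joint_amplitude")
        if not 0 <= self.func_fraction <= 1:
            raise ValueError("func_fraction must be in [0, 1]")

    def grid(self) -> SphericalGrid:
        return make_grid(self.n_lat, self.n_lon)


@dataclass
class SyntheticSubject:
    """One simulated subject with its generative ground truth."""

    features: FeatureMap  # channels (geometric, functional)
    true_v_j: VelocityField
    true_v_g: VelocityField
    true_v_f: VelocityField
    noise_j: np.ndarray  # stage-1 noise on (geom, func) channels
    noise_g: np.ndarray  # stage-2 noise on the geometric channel
    noise_f: np.ndarray  # stage-2 noise on the functional channel

    @property
    def has_functional(self) -> bool:
        return bool(self.features.valid_mask[1])

    def true_phi_j(self, n_steps: int = 7) -> DeformationField:
        return integrate_svf(self.true_v_j, n_steps)


@dataclass
class SyntheticCohort:
    config: GenerativeConfig
    atlas: FeatureMap
    subjects: list[SyntheticSubject] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.subjects)


def _ridge_maxima(geom: np.ndarray, n: int) -> np.ndarray:
    """Grid positions of the n strongest local maxima of the folding pattern."""
    from scipy.ndimage import maximum_filter

    wrapped_max = maximum_filter(geom, size=5, mode=("nearest", "wrap"))
    peaks = np.argwhere((geom == wrapped_max))
    order = np.argsort(geom[tuple(peaks.T)])[::-1]
    # drop duplicate plateau hits close to an already-kept peak
    kept: list[np.ndarray] = []
    for p in peaks[order]:
        if all(max(abs(p[0] - q[0]), abs(p[1] - q[1])) > 3 for q in kept):
            kept.append(p)
        if len(kept) == n:
            break
    return np.array(kept)


def make_true_atlas(config: GenerativeConfig) -> FeatureMap:
    """Known two-channel atlas: sinusoidal folds + offset functional blobs."""
    grid = config.grid()
    theta = grid.theta[:, None]
    phi = grid.phi[None, :]
    # several incommensurate angular harmonics: banded like curvature, but
    # with no longitudinal rotation mapping the pattern onto itself, so the
    # atlas frame is identifiable (no gauge freedom for a learned template)
    geom = (np.sin(4.0 * theta) * np.cos(3.0 * phi)
            + 0.6 * np.sin(3.0 * theta) * np.cos(2.0 * phi + 1.0)
            + 0.4 * np.sin(5.0 * theta) * np.cos(5.0 * phi + 2.1))
    geom = geom - np.median(geom)

    centers = _ridge_maxima(geom, config.n_blobs)
    rows = np.arange(config.n_lat, dtype=float)[:, None]
    cols = np.arange(config.n_lon, dtype=float)[None, :]
    func = np.zeros_like(geom)
    for r0, c0 in centers:
        c_shift = (c0 + config.func_offset) % config.n_lon
        dc = np.abs(cols - c_shift)
        dc = np.minimum(dc, config.n_lon - dc)  # periodic longitude distance
        d2 = (rows - r0) ** 2 + dc**2
        func += np.exp(-d2 / (2.0 * config.blob_width**2))
    return FeatureMap(grid, np.stack([geom, func]), (GEOMETRIC, FUNCTIONAL))


def sample_smooth_velocity(
    grid: SphericalGrid, amplitude: float, smoothness_scale: float,
    rng: np.random.Generator,
) -> VelocityField:
    """Smoothed white noise, tapered toward the poles, peak speed = amplitude.

    The sin(theta) taper makes the sampled flows vanish at the latitude
    boundary of the parameterization - cross-pole translation is not a
    motion the spherical model represents - keeping every simulated
    deformation well-posed for recovery.
    """
    if amplitude == 0.0:
        return VelocityField(grid, np.zeros((2, *grid.shape)))
    white = rng.standard_normal((2, *grid.shape))
    v = gaussian_filter(white, sigma=(0, smoothness_scale, smoothness_scale),
                        mode=("constant", "nearest", "wrap"))
    v *= np.sin(grid.theta)[None, :, None]
    speed = np.sqrt(v[0] ** 2 + v[1] ** 2)
    peak = speed.max()
    if peak > 0:
        v *= amplitude / peak
    return VelocityField(grid, v)


def sample_subject(
    atlas: FeatureMap, config: GenerativeConfig, rng: np.random.Generator,
    v_j: VelocityField | None = None, with_functional: bool = True,
) -> SyntheticSubject:
    """Draw one subject through the two-stage noisy-warp model.

    ``v_j`` may be supplied (antithetic cohort centering); the modality
    velocities and all noise stages are always drawn from ``rng``.
    """
    grid = atlas.grid
    if v_j is None:
        v_j = sample_smooth_velocity(grid, config.joint_amplitude,
                                     config.smoothness_scale, rng)
    v_g = sample_smooth_velocity(grid, config.modality_amplitude,
                                 config.smoothness_scale, rng)
    v_f = sample_smooth_velocity(grid, config.modality_amplitude,
                                 config.smoothness_scale, rng)

    phi_j = integrate_svf(v_j, config.int_steps)
    noise_j = rng.normal(0.0, config.sigma_noise, atlas.values.shape) \
        if config.sigma_noise > 0 else np.zeros(atlas.values.shape)
    joint = warp_array(atlas.values, phi_j.u) + noise_j

    phi_g = integrate_svf(v_g, config.int_steps)
    phi_f = integrate_svf(v_f, config.int_steps)
    noise_g = rng.normal(0.0, config.sigma_noise, grid.shape) \
        if config.sigma_noise > 0 else np.zeros(grid.shape)
    noise_f = rng.normal(0.0, config.sigma_noise, grid.shape) \
        if config.sigma_noise > 0 else np.zeros(grid.shape)
    i_g = warp_array(joint[0], phi_g.u) + noise_g
    i_f = warp_array(joint[1], phi_f.u) + noise_f

    valid = np.array([True, bool(with_functional)])
    features = FeatureMap(grid, np.stack([i_g, i_f]), (GEOMETRIC, FUNCTIONAL), valid)
    return SyntheticSubject(
        features=features, true_v_j=v_j, true_v_g=v_g, true_v_f=v_f,
        noise_j=noise_j, noise_g=noise_g, noise_f=noise_f,
    )


def make_cohort(config: GenerativeConfig, seed: int | None = None) -> SyntheticCohort:
    """Simulate a full cohort; same config + seed reproduces it bit-identically.

    With ``centered``, joint velocities are drawn in antithetic +v/-v pairs
    so the cohort-mean joint velocity vanishes (an odd trailing subject gets
    v_j = 0), emulating a population already centered on its atlas.  A
    ``func_fraction`` < 1 marks the complementary rounded share of subjects
    as lacking functional maps (semi-supervised training).
    """
    if config.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(
        config.seed if seed is None else seed))
    atlas = make_true_atlas(config)
    grid = atlas.grid
    n = config.n_subjects

    joint_fields: list[VelocityField | None]
    if config.centered:
        joint_fields = []
        while len(joint_fields) < n - 1:
            v = sample_smooth_velocity(grid, config.joint_amplitude,
                                       config.smoothness_scale, rng)
            joint_fields.extend([v, VelocityField(grid, -v.v)])
        if len(joint_fields) < n:
            joint_fields.append(VelocityField(grid, np.zeros((2, *grid.shape))))
        joint_fields = joint_fields[:n]
    else:
        joint_fields = [None] * n

    n_func = int(round(config.func_fraction * n))
    has_func = np.zeros(n, dtype=bool)
    has_func[rng.permutation(n)[:n_func]] = True

    subjects = [
        sample_subject(atlas, config, rng, v_j=joint_fields[i],
                       with_functional=bool(has_func[i]))
        for i in range(n)
    ]
    return SyntheticCohort(config=config, atlas=atlas, subjects=subjects)
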