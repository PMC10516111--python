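"""Diffeomorphism algebra: integration, composition, warping, Jacobians."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from cortalign.deformation import (DeformationField, VelocityField, compose,
                                   integrate_svf, invert, jacobian_determinant,
                                   negative_jacobian_fraction, warp)
from cortalign.grid import GEOMETRIC, FeatureMap, make_grid, standardize
from cortalign.interp import sample_channels


def smooth_velocity(grid, amplitude, rng, scale=3.0):
    """Random smooth test velocity, tapered to zero toward the poles."""
    white = rng.standard_normal((2, *grid.shape))
    v = gaussian_filter(white, sigma=(0, scale, scale), mode=("constant", "nearest", "wrap"))
    v *= np.sin(grid.theta)[None, :, None]
    speed = np.hypot(v[0], v[1])
    v *= amplitude / speed.max()
    return VelocityField(grid, v)


def euler_flow(v, n=1024):
    """Fine-step explicit Euler integration of dx/dt = v(x), the oracle."""
    grid = v.grid
    rr, cc = np.meshgrid(np.arange(grid.n_lat, dtype=float),
                         np.arange(grid.n_lon, dtype=float), indexing="ij")
    r, c = rr.copy(), cc.copy()
    dt = 1.0 / n
    for _ in range(n):
        vel = sample_channels(v.v, r, c)
        r = r + dt * vel[0]
        c = c + dt * vel[1]
    return np.stack([r - rr, c - cc])


class TestIntegrateSvf:
    def test_zero_velocity_gives_identity(self, medium_grid):
        phi = integrate_svf(VelocityField(medium_grid, np.zeros((2, 16, 32))))
        assert np.all(phi.u == 0.0)

    def test_constant_longitudinal_velocity_translates(self, medium_grid):
        c = 2.5
        v = np.zeros((2, 16, 32))
        v[1] = c
        phi = integrate_svf(VelocityField(medium_grid, v))
        assert np.allclose(phi.u[0], 0.0, atol=1e-9)
        assert np.allclose(phi.u[1], c, atol=1e-9)

    def test_matches_fine_step_euler_oracle(self, rng):
        # resolution chosen so bilinear interpolation error sits below the
        # 1e-2 tolerance; peak speed 1.5 cells
        grid = make_grid(32, 64)
        v = smooth_velocity(grid, 1.5, rng, scale=8.0)
        phi = integrate_svf(v, 7)
        ref = euler_flow(v, 1024)
        assert np.abs(phi.u - ref).max() < 1e-2

    def test_step_count_convergence(self, rng):
        grid = make_grid(32, 64)
        v = smooth_velocity(grid, 1.5, rng, scale=8.0)
        u7 = integrate_svf(v, 7).u
        u9 = integrate_svf(v, 9).u
        assert np.abs(u7 - u9).max() < 1e-3

    def test_rejects_bad_input(self, medium_grid):
        v = np.zeros((2, 16, 32))
        with pytest.raises(ValueError):
            integrate_svf(VelocityField(medium_grid, v), n_steps=0)
        v[0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            VelocityField(medium_grid, v)


class TestCompose:
    def test_identity_laws(self, medium_grid, rng):
        phi = integrate_svf(smooth_velocity(medium_grid, 1.5, rng))
        ident = DeformationField.identity(medium_grid)
        assert np.allclose(compose(phi, ident).u, phi.u)
        assert np.allclose(compose(ident, phi).u, phi.u)

    def test_integer_translations_add_modulo_width(self, medium_grid):
        def translation(k):
            u = np.zeros((2, 16, 32))
            u[1] = k
            return DeformationField(medium_grid, u)

        out = compose(translation(30), translation(5))
        fm = FeatureMap(medium_grid, np.arange(512, dtype=float).reshape(1, 16, 32),
                        (GEOMETRIC,))
        # sampling through the composed map equals a circular shift by 35 mod 32
        assert np.allclose(warp(fm, out).values[0], np.roll(fm.values[0], -3, axis=1))

    def test_inverse_consistency(self, medium_grid, rng):
        v = smooth_velocity(medium_grid, 1.5, rng)
        comp = compose(integrate_svf(v), integrate_svf(VelocityField(medium_grid, -v.v)))
        assert np.abs(comp.u).mean() < 0.05

    def test_associative_within_tolerance(self, rng):
        # gentle fields on a fine grid: resampling error below 1e-4
        grid = make_grid(64, 128)
        a, b, c = (integrate_svf(smooth_velocity(grid, 0.1, rng, scale=12.0))
                   for _ in range(3))
        left = compose(compose(a, b), c)
        right = compose(a, compose(b, c))
        assert np.abs(left.u - right.u).max() < 1e-4

    def test_grid_mismatch_raises(self, medium_grid, small_grid):
        with pytest.raises(ValueError):
            compose(DeformationField.identity(medium_grid),
                    DeformationField.identity(small_grid))


class TestWarp:
    def test_identity_is_bitwise_equal(self, small_grid, rng):
        fm = FeatureMap(small_grid, rng.standard_normal((2, 8, 16)),
                        (GEOMETRIC, GEOMETRIC))
        out = warp(fm, DeformationField.identity(small_grid))
        assert np.array_equal(out.values, fm.values)

    def test_integer_shift_is_exact_circular_shift(self, small_grid, rng):
        fm = FeatureMap(small_grid, rng.standard_normal((1, 8, 16)), (GEOMETRIC,))
        u = np.zeros((2, 8, 16))
        u[1] = 3
        out = warp(fm, DeformationField(small_grid, u))
        assert np.allclose(out.values[0], np.roll(fm.values[0], -3, axis=1))

    def test_matches_scalar_loop_oracle(self, small_grid, rng):
        fm = FeatureMap(small_grid, rng.standard_normal((1, 8, 16)), (GEOMETRIC,))
        u = rng.standard_normal((2, 8, 16)) * 2.0
        out = warp(fm, DeformationField(small_grid, u))
        expected = np.empty((8, 16))
        vals = fm.values[0]
        for i in range(8):
            for j in range(16):
                r = np.clip(i + u[0, i, j], 0, 7)
                c = (j + u[1, i, j]) % 16
                r0 = min(int(np.floor(r)), 6)
                c0 = int(np.floor(c)) % 16
                fr, fc = r - r0, c - np.floor(c)
                c1 = (c0 + 1) % 16
                expected[i, j] = ((1 - fr) * (1 - fc) * vals[r0, c0]
                                  + (1 - fr) * fc * vals[r0, c1]
                                  + fr * (1 - fc) * vals[r0 + 1, c0]
                                  + fr * fc * vals[r0 + 1, c1])
        assert np.abs(out.values[0] - expected).max() < 1e-6


def folded_field(grid):
    """A hand-built field that smoothly swaps two rows, folding the map."""
    u = np.zeros((2, *grid.shape))
    rows = np.arange(grid.n_lat)
    bump = np.exp(-((rows - grid.n_lat / 2) ** 2) / 2.0)
    u[0] = -3.0 * bump[:, None]  # strong opposing row displacement
    u[0, grid.n_lat // 2 - 2:grid.n_lat // 2] = 2.0
    return DeformationField(grid, u)


class TestJacobian:
    def test_identity_has_unit_determinant(self, medium_grid):
        det = jacobian_determinant(DeformationField.identity(medium_grid))
        assert np.allclose(det, 1.0)

    def test_linear_row_ramp(self, medium_grid):
        u = np.zeros((2, 16, 32))
        u[0] = 0.1 * np.arange(16)[:, None]
        det = jacobian_determinant(DeformationField(medium_grid, u))
        assert np.allclose(det[1:-1], 1.1)

    def test_fold_detected_by_orientation_oracle(self, medium_grid):
        phi = folded_field(medium_grid)
        det = jacobian_determinant(phi)
        # brute-force orientation test: the signed area of the mapped cell
        # spanned by central-difference edge vectors flips where it folds
        r_map = np.arange(16, dtype=float)[:, None] + phi.u[0]
        c_map = np.arange(32, dtype=float)[None, :] + phi.u[1]
        c_map = np.broadcast_to(c_map, (16, 32))
        dr_r = np.gradient(r_map, axis=0)
        dc_c = np.ones_like(c_map)
        signed = dr_r * dc_c  # pure-row deformation: area sign = dr_r
        inner = (slice(1, -1), slice(None))
        assert np.array_equal(det[inner] <= 0, signed[inner] <= 0)
        assert (det <= 0).any()

    def test_negative_fraction_counts_folded_cells(self, medium_grid):
        phi = folded_field(medium_grid)
        det = jacobian_determinant(phi)
        manual = 100.0 * int((det <= 0).sum()) / det.size
        assert negative_jacobian_fraction(phi) == pytest.approx(manual)

    def test_identity_fraction_zero(self, medium_grid):
        assert negative_jacobian_fraction(DeformationField.identity(medium_grid)) == 0.0

    @pytest.mark.parametrize("amplitude", [0.3, 1.0])
    def test_small_svf_flows_never_fold(self, medium_grid, rng, amplitude):
        for _ in range(3):
            v = smooth_velocity(medium_grid, amplitude, rng)
            phi = integrate_svf(v)
            assert negative_jacobian_fraction(phi) == 0.0


class TestInvert:
    def test_zero_velocity(self, medium_grid):
        phi = invert(VelocityField(medium_grid, np.zeros((2, 16, 32))))
        assert np.all(phi.u == 0.0)

    def test_constant_velocity_negates_translation(self, medium_grid):
        v = np.zeros((2, 16, 32))
        v[1] = 1.75
        phi = invert(VelocityField(medium_grid, v))
        assert np.allclose(phi.u[1], -1.75, atol=1e-9)
        assert np.allclose(phi.u[0], 0.0, atol=1e-9)

    def test_round_trip_on_features(self, rng):
        grid = make_grid(32, 64)
        v = smooth_velocity(grid, 1.5, rng, scale=8.0)
        fm = standardize(FeatureMap(
            grid,
            gaussian_filter(rng.standard_normal((1, 32, 64)), (0, 4, 4),
                            mode=("constant", "nearest", "wrap")),
            (GEOMETRIC,),
        ))
        back = warp(warp(fm, integrate_svf(v)), invert(v))
        assert np.abs(back.values - fm.values).mean() < 0.02
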