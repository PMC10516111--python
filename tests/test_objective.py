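"""Objective components against explicit-summation oracles."""

import numpy as np
import pytest

from cortalign.deformation import VelocityField, integrate_svf, warp
from cortalign.grid import FUNCTIONAL, GEOMETRIC, FeatureMap
from cortalign.objective import (LossWeights, centrality_penalty, similarity_loss,
                                 smoothness_penalty, total_loss)


class _Fields:
    """Minimal predicted-fields stand-in carrying velocities."""

    def __init__(self, grid, v_j, v_g, v_f):
        self.v_j = VelocityField(grid, v_j)
        self.v_g = VelocityField(grid, v_g)
        self.v_f = VelocityField(grid, v_f)


class _Atlas:
    def __init__(self, geom, func):
        self.geometric_values = geom
        self.functional_values = func


def smoothness_oracle(u, lam, w):
    """Loop-based forward-difference penalty, the independent reference."""
    n_lat, n_lon = u.shape[1:]
    num = 0.0
    den = 0.0
    for comp in range(2):
        for i in range(n_lat - 1):
            for j in range(n_lon):
                num += w[i, j] * (u[comp, i + 1, j] - u[comp, i, j]) ** 2
        for i in range(n_lat):
            for j in range(n_lon):
                num += w[i, j] * (u[comp, i, (j + 1) % n_lon] - u[comp, i, j]) ** 2
    den = 2.0 * (w[:-1].sum() + w.sum())
    return lam * num / den


class TestSmoothness:
    def test_zero_field(self, small_grid, small_weights):
        assert smoothness_penalty(np.zeros((2, 8, 16)), 0.1, small_weights) == 0.0

    def test_translation_unpenalized(self, small_grid, small_weights):
        u = np.full((2, 8, 16), 3.7)
        assert smoothness_penalty(u, 0.5, small_weights) == pytest.approx(0.0, abs=1e-12)

    def test_matches_loop_oracle(self, small_grid, small_weights, rng):
        u = rng.standard_normal((2, 8, 16))
        got = smoothness_penalty(u, 0.2, small_weights)
        want = smoothness_oracle(u, 0.2, small_weights.w)
        assert got == pytest.approx(want, abs=1e-8)

    def test_column_ramp_wrap_aware(self, small_grid, small_weights):
        # a mod-aware column ramp: constant gradient except at the seam
        u = np.zeros((2, 8, 16))
        u[0] = 0.3 * np.arange(16)[None, :]
        got = smoothness_penalty(u, 1.0, small_weights)
        want = smoothness_oracle(u, 1.0, small_weights.w)
        assert got == pytest.approx(want, abs=1e-8)


class TestCentrality:
    def test_antisymmetric_batch_vanishes(self, rng):
        u = rng.standard_normal((2, 8, 16))
        assert centrality_penalty([u, -u], 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_single_element(self, rng):
        u = rng.standard_normal((2, 8, 16))
        assert centrality_penalty([u], 0.3) == pytest.approx(0.3 * (u**2).mean())

    def test_matches_brute_force(self, rng):
        batch = [rng.standard_normal((2, 8, 16)) for _ in range(8)]
        mean = sum(batch) / 8.0
        want = 0.01 * (mean**2).mean()
        assert centrality_penalty(batch, 0.01) == pytest.approx(want, abs=1e-8)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            centrality_penalty([], 0.1)


class TestSimilarity:
    def test_identical_maps(self, small_grid, small_weights, rng):
        vals = rng.standard_normal((1, 8, 16))
        fm = FeatureMap(small_grid, vals, (GEOMETRIC,))
        assert similarity_loss(fm, fm, small_weights) == 0.0

    def test_constant_difference_unit_weights(self, small_grid, rng):
        from cortalign.grid import WeightMap

        w1 = WeightMap(small_grid, np.ones((8, 16)))
        a = FeatureMap(small_grid, rng.standard_normal((1, 8, 16)), (GEOMETRIC,))
        b = FeatureMap(small_grid, a.values + 0.7, (GEOMETRIC,))
        assert similarity_loss(a, b, w1) == pytest.approx(0.49, abs=1e-12)

    def test_matches_weighted_sum_oracle(self, small_grid, small_weights, rng):
        a = FeatureMap(small_grid, rng.standard_normal((2, 8, 16)),
                       (GEOMETRIC, FUNCTIONAL))
        b = FeatureMap(small_grid, rng.standard_normal((2, 8, 16)),
                       (GEOMETRIC, FUNCTIONAL))
        w = small_weights.w
        want = 0.0
        for c in range(2):
            num = 0.0
            for i in range(8):
                for j in range(16):
                    num += w[i, j] * (a.values[c, i, j] - b.values[c, i, j]) ** 2
            want += num / w.sum()
        want /= 2.0
        assert similarity_loss(a, b, small_weights) == pytest.approx(want, abs=1e-8)

    def test_no_valid_channels_rejected(self, small_grid, small_weights, rng):
        a = FeatureMap(small_grid, rng.standard_normal((1, 8, 16)), (GEOMETRIC,),
                       np.array([False]))
        with pytest.raises(ValueError):
            similarity_loss(a, a, small_weights)


class TestLossWeights:
    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError):
            LossWeights(w_func=0.7, w_geom=0.4)
        with pytest.raises(ValueError):
            LossWeights(lambda_j=-0.1)


def _random_batch(grid, rng, n=3, with_func=True):
    from scipy.ndimage import gaussian_filter

    subjects, fields = [], []
    for _ in range(n):
        vals = gaussian_filter(rng.standard_normal((2, *grid.shape)), (0, 2, 2),
                               mode=("constant", "nearest", "wrap"))
        mask = np.array([True, with_func])
        subjects.append(FeatureMap(grid, vals, (GEOMETRIC, FUNCTIONAL), mask))
        vs = [gaussian_filter(rng.standard_normal((2, *grid.shape)), (0, 3, 3),
                              mode=("constant", "nearest", "wrap")) * 0.5
              for _ in range(3)]
        fields.append(_Fields(grid, *vs))
    return subjects, fields


class TestTotalLoss:
    def test_perfect_fit_limit(self, small_grid, small_weights):
        atlas_vals = np.stack([np.sin(np.arange(128)).reshape(8, 16),
                               np.cos(np.arange(128)).reshape(8, 16)])
        atlas = _Atlas(atlas_vals[:1], atlas_vals[1:])
        subj = FeatureMap(small_grid, atlas_vals, (GEOMETRIC, FUNCTIONAL))
        zero = np.zeros((2, 8, 16))
        fields = [_Fields(small_grid, zero, zero, zero)]
        weights = LossWeights(alpha_j=0.0)
        rep = total_loss([subj], fields, atlas, weights, small_weights)
        assert rep.total == pytest.approx(0.0, abs=1e-10)
        assert rep.sim_geom_atlas == 0.0 and rep.sim_func_subject == 0.0

    def test_geometric_only_batch(self, small_grid, small_weights, rng):
        subjects, fields = _random_batch(small_grid, rng, n=2, with_func=False)
        atlas = _Atlas(rng.standard_normal((1, 8, 16)), rng.standard_normal((1, 8, 16)))
        rep = total_loss(subjects, fields, atlas, LossWeights(), small_weights)
        assert rep.n_func_observed == 0
        assert rep.sim_func_atlas == 0.0 and rep.sim_func_subject == 0.0
        assert rep.total == pytest.approx(rep.recombined_total(LossWeights()), abs=1e-6)

    def test_report_recomposes_to_total(self, small_grid, small_weights, rng):
        subjects, fields = _random_batch(small_grid, rng, n=3)
        atlas = _Atlas(rng.standard_normal((1, 8, 16)), rng.standard_normal((1, 8, 16)))
        weights = LossWeights()
        rep = total_loss(subjects, fields, atlas, weights, small_weights)
        assert rep.n_func_observed == 3
        assert rep.total == pytest.approx(rep.recombined_total(weights), abs=1e-6)

    def test_smoothness_weight_scales_linearly_and_leaves_similarity(self,
                                                                     small_grid,
                                                                     small_weights,
                                                                     rng):
        subjects, fields = _random_batch(small_grid, rng, n=2)
        atlas = _Atlas(rng.standard_normal((1, 8, 16)), rng.standard_normal((1, 8, 16)))
        w1 = LossWeights(lambda_j=0.1)
        w2 = LossWeights(lambda_j=0.2)
        r1 = total_loss(subjects, fields, atlas, w1, small_weights)
        r2 = total_loss(subjects, fields, atlas, w2, small_weights)
        assert r2.smooth_j == pytest.approx(2.0 * r1.smooth_j, rel=1e-10)
        for name in ("sim_geom_atlas", "sim_geom_subject", "sim_func_atlas",
                     "sim_func_subject", "smooth_g", "smooth_f", "central_j"):
            assert getattr(r1, name) == pytest.approx(getattr(r2, name), rel=1e-12)

    def test_functional_masking_ignores_absent_subjects(self, small_grid,
                                                        small_weights, rng):
        subjects, fields = _random_batch(small_grid, rng, n=3)
        atlas = _Atlas(rng.standard_normal((1, 8, 16)), rng.standard_normal((1, 8, 16)))
        weights = LossWeights()
        base = total_loss(subjects, fields, atlas, weights, small_weights)
        # add one subject without functional data; its (present but invalid)
        # functional values must never reach the functional terms
        extra_s, extra_f = _random_batch(small_grid, rng, n=1, with_func=False)
        rep = total_loss(subjects + extra_s, fields + extra_f, atlas, weights,
                         small_weights)
        assert rep.n_func_observed == 3
        assert rep.sim_func_atlas == pytest.approx(base.sim_func_atlas, rel=1e-9)
        assert rep.sim_func_subject == pytest.approx(base.sim_func_subject, rel=1e-9)

    def test_dual_space_terms_match_manual_warp_oracle(self, small_grid,
                                                       small_weights, rng):
        """Subject/atlas-space similarity recomputed with the numpy algebra."""
        from cortalign.deformation import compose, invert
        from cortalign.objective import similarity_loss

        subjects, fields = _random_batch(small_grid, rng, n=2)
        atlas_g = np.tanh(rng.standard_normal((1, 8, 16)))
        atlas = _Atlas(atlas_g, rng.standard_normal((1, 8, 16)))
        weights = LossWeights()
        rep = total_loss(subjects, fields, atlas, weights, small_weights)

        acc = 0.0
        for s, f in zip(subjects, fields):
            psi = compose(integrate_svf(f.v_j), integrate_svf(f.v_g))
            model_img = FeatureMap(
                small_grid,
                np.stack([warp(FeatureMap(small_grid, atlas_g, (GEOMETRIC,)),
                               psi).values[0]]),
                (GEOMETRIC,),
            )
            obs = FeatureMap(small_grid, s.values[:1], (GEOMETRIC,))
            acc += similarity_loss(obs, model_img, small_weights)
        assert rep.sim_geom_subject == pytest.approx(acc / 2.0, abs=1e-9)

        acc = 0.0
        for s, f in zip(subjects, fields):
            psi_inv = compose(invert(f.v_g), invert(f.v_j))
            back = warp(FeatureMap(small_grid, s.values[:1], (GEOMETRIC,)), psi_inv)
            ref = FeatureMap(small_grid, atlas_g, (GEOMETRIC,))
            acc += similarity_loss(ref, back, small_weights)
        assert rep.sim_geom_atlas == pytest.approx(acc / 2.0, abs=1e-9)
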