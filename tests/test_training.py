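"""Scheduler, augmentation and the training loop."""

from dataclasses import replace

import numpy as np
import pytest

from cortalign.grid import FUNCTIONAL, GEOMETRIC, FeatureMap, make_grid
from cortalign.network import NetworkConfig, build_model
from cortalign.objective import LossWeights
from cortalign.synthetic import GenerativeConfig, make_cohort
from cortalign.training import (TrainConfig, TrainState, augment_batch, lr_at,
                                register_validation, train)

SMALL_GEN = GenerativeConfig(n_lat=16, n_lon=32, n_subjects=8, joint_amplitude=2.0,
                             modality_amplitude=0.6, smoothness_scale=3.0,
                             sigma_noise=0.25, n_blobs=2, seed=21)


def small_model(seed=0, **cfg_overrides):
    cfg = NetworkConfig.desk_scale(16, **cfg_overrides)
    return build_model(cfg, make_grid(16, 32), 1, 1, seed=seed)


class TestLearningRateSchedule:
    def test_published_endpoints(self):
        cfg = TrainConfig()
        assert lr_at(TrainState(epoch=0), cfg) == pytest.approx(1e-3)
        assert lr_at(TrainState(epoch=500), cfg) == pytest.approx(1e-4)

    def test_linear_midpoint(self):
        cfg = TrainConfig()
        assert lr_at(TrainState(epoch=250), cfg) == pytest.approx(5.5e-4)

    def test_plateau_cuts_by_factor_after_linear_phase(self):
        cfg = TrainConfig(plateau_patience=3)
        state = TrainState(epoch=400)
        register_validation(state, 1.0, cfg)
        # stagnation during the linear phase must not trigger plateau cuts
        for e in range(401, 404):
            state.epoch = e
            register_validation(state, 2.0, cfg)
        assert state.plateau_events == 0
        state.epoch = 501
        for e in range(501, 504):
            state.epoch = e
            register_validation(state, 2.0, cfg)
        assert state.plateau_events == 1
        assert lr_at(state, cfg) == pytest.approx(1e-4 * 0.9)

    def test_improvement_resets_counter(self):
        cfg = TrainConfig(plateau_patience=2)
        state = TrainState(epoch=600)
        register_validation(state, 1.0, cfg)
        state.epoch = 601
        register_validation(state, 2.0, cfg)
        state.epoch = 602
        assert register_validation(state, 0.5, cfg)  # new best
        assert state.since_improve == 0 and state.plateau_events == 0


class TestAugmentation:
    def _maps(self, rng, n=3, equal_channels=False):
        grid = make_grid(16, 32)
        out = []
        for _ in range(n):
            g = rng.standard_normal((16, 32))
            f = g.copy() if equal_channels else rng.standard_normal((16, 32))
            out.append(FeatureMap(grid, np.stack([g, f]), (GEOMETRIC, FUNCTIONAL)))
        return out

    def test_disabled_augmentation_is_identity(self, rng):
        cfg = TrainConfig(warp_aug_sigma=0.0, noise_aug_geom=0.0, noise_aug_func=0.0)
        batch = self._maps(rng)
        out = augment_batch(batch, cfg, rng)
        for a, b in zip(out, batch):
            assert np.array_equal(a.values, b.values)

    def test_geometric_noise_sd_calibrated(self, rng):
        cfg = TrainConfig(warp_aug_sigma=0.0, noise_aug_geom=1.0, noise_aug_func=0.0)
        grid = make_grid(64, 128)
        base = FeatureMap(grid, np.zeros((1, 64, 128)), (GEOMETRIC,))
        noise = []
        for _ in range(13):  # > 1e5 cells
            noise.append(augment_batch([base], cfg, rng)[0].values[0])
        sd = np.concatenate([n.ravel() for n in noise]).std()
        assert sd == pytest.approx(1.0, rel=0.02)

    def test_channels_of_one_subject_share_the_warp(self, rng):
        cfg = TrainConfig(warp_aug_sigma=4.0, noise_aug_geom=0.0, noise_aug_func=0.0)
        batch = self._maps(rng, equal_channels=True)
        out = augment_batch(batch, cfg, rng)
        changed = 0
        for a, b in zip(out, batch):
            assert np.allclose(a.values[0], a.values[1])  # identical warp
            changed += not np.array_equal(a.values, b.values)
        assert changed == len(batch)

    def test_absent_channels_untouched(self, rng):
        grid = make_grid(16, 32)
        vals = rng.standard_normal((2, 16, 32))
        fm = FeatureMap(grid, vals, (GEOMETRIC, FUNCTIONAL), np.array([True, False]))
        cfg = TrainConfig(warp_aug_sigma=0.0, noise_aug_geom=1.0, noise_aug_func=6.0)
        out = augment_batch([fm], cfg, rng)[0]
        assert np.array_equal(out.values[1], vals[1])
        assert not np.array_equal(out.values[0], vals[0])


class TestTrainLoop:
    def test_single_epoch_smoke(self):
        cohort = make_cohort(SMALL_GEN)
        res = train(small_model(), cohort, TrainConfig.reference(
            epochs=1, batch_size=4, val_fraction=0.25, seed=0))
        assert len(res.history) == 1
        assert np.isfinite(res.history.train_total.iloc[0])
        assert np.isfinite(res.history.val_total.iloc[0])

    def test_cohort_smaller_than_batch_rejected(self):
        cohort = make_cohort(replace(SMALL_GEN, n_subjects=3))
        with pytest.raises(ValueError):
            train(small_model(), cohort, TrainConfig(batch_size=8))

    def test_training_reduces_loss(self):
        cohort = make_cohort(SMALL_GEN)
        res = train(small_model(seed=3), cohort, TrainConfig.reference(
            epochs=40, batch_size=4, val_fraction=0.25, seed=3))
        first = res.history.train_total.iloc[0]
        last = res.history.train_total.iloc[-5:].mean()
        assert last < 0.75 * first  # short run on a tiny config: clear descent

    def test_reference_schedule_halves_initial_loss(self, reference_run):
        """Under the reference conditions (200 epochs, desk-scale network,
        default synthetic cohort) the final training loss falls below half
        of the first epoch's."""
        _, result = reference_run
        h = result.history
        assert h.train_total.iloc[-1] < 0.5 * h.train_total.iloc[0]

    def test_seeded_run_is_bit_reproducible(self):
        cohort = make_cohort(SMALL_GEN)
        cfg = TrainConfig.reference(epochs=3, batch_size=4, val_fraction=0.25, seed=9)
        r1 = train(small_model(seed=2), cohort, cfg)
        r2 = train(small_model(seed=2), cohort, cfg)
        assert np.array_equal(r1.history.train_total.values,
                              r2.history.train_total.values)
        assert np.array_equal(r1.model.atlas.geometric.data,
                              r2.model.atlas.geometric.data)

    def test_functional_free_cohort_matches_geometric_only_training(self):
        """Dropping all functional maps leaves the loss trajectory identical
        to a cohort that never had them - semi-supervision degrades
        gracefully."""
        cohort_full = make_cohort(replace(SMALL_GEN, func_fraction=0.0))
        cfg = TrainConfig.reference(epochs=3, batch_size=4, val_fraction=0.25, seed=4)
        r1 = train(small_model(seed=1), cohort_full, cfg)
        # strip functional channels entirely
        maps_only = []
        for s in cohort_full.subjects:
            fm = s.features
            maps_only.append(FeatureMap(fm.grid, fm.values[:1], (GEOMETRIC,)))
        r2 = train(small_model(seed=1), maps_only, cfg)
        assert np.allclose(r1.history.train_total.values,
                           r2.history.train_total.values, rtol=1e-6)
        assert (r1.history.n_func_observed == 0).all()

    def test_frozen_atlas_stays_fixed(self):
        cohort = make_cohort(SMALL_GEN)
        model = small_model(seed=5)
        before = model.atlas.geometric.data.copy()
        train(model, cohort, TrainConfig.reference(
            epochs=2, batch_size=4, val_fraction=0.25, seed=5, atlas_frozen=True,
            restore_best=False))
        assert np.array_equal(model.atlas.geometric.data, before)

    def test_centrality_weight_shrinks_mean_joint_displacement(self):
        """With the centrality prior the batch-mean joint displacement at the
        end of training is smaller than without it (two seeds)."""
        cohort = make_cohort(replace(SMALL_GEN, centered=False))

        def mean_disp(alpha, seed):
            model = small_model(seed=seed)
            train(model, cohort, TrainConfig.reference(
                epochs=30, batch_size=8, val_fraction=0.0, seed=seed,
                restore_best=False),
                loss_weights=LossWeights(alpha_j=alpha))
            from cortalign.grid import standardize

            fields = [model.predict_fields(
                standardize(s.features).select(GEOMETRIC)) for s in cohort.subjects]
            u_bar = np.mean([f.phi_j.u for f in fields], axis=0)
            return np.sqrt((u_bar**2).mean())

        for seed in (0, 1):
            assert mean_disp(0.05, seed) < mean_disp(0.0, seed)
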