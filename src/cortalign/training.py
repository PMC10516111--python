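"""Semi-supervised training loop: augmentation, scheduling, Adam, checkpoints.

The learning-rate schedule follows the published recipe: linear decay from
1e-3 to 1e-4 over the first 500 epochs, then a multiplicative 0.9 cut each
time 100 consecutive epochs pass without a validation improvement.
Augmentation adds a shared random smooth warp per subject (identical for the
geometric and functional maps, longitude component scaled by 1/sin(theta) so
the on-sphere displacement sd is uniform) and per-modality Gaussian noise.
Subjects lacking functional maps contribute geometric terms only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .autodiff import Tensor, tensor
from .grid import FeatureMap, distortion_weights, standardize
from .network import RegistrationModel
from .objective import LossReport, LossWeights, total_loss_tensors

__all__ = ["TrainConfig", "TrainState", "Adam", "augment_batch", "lr_at",
           "register_validation", "train", "TrainResult"]


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the published recipe)."""

    batch_size: int = 8
    lr_init: float = 1e-3
    lr_floor: float = 1e-4
    linear_phase_epochs: int = 500
    plateau_factor: float = 0.9
    plateau_patience: int = 100
    warp_aug_sigma: float = 4.0
    warp_aug_smooth: float = 8.0
    noise_aug_geom: float = 1.0
    noise_aug_func: float = 6.0
    epochs: int = 200
    seed: int = 0
    atlas_lr_multiplier: float = 10.0
    atlas_frozen: bool = False
    val_fraction: float = 0.2
    int_steps: int = 7
    restore_best: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.lr_floor <= self.lr_init):
            raise ValueError("require 0 < lr_floor <= lr_init")
        if self.plateau_patience < 1:
            raise ValueError("plateau_patience must be >= 1")

    @classmethod
    def reference(cls, **overrides) -> "TrainConfig":
        """Conditions used for the synthetic reference-cohort experiments.

        Augmentation is disabled: the generative simulator already supplies
        the population variability and matched observation noise that the
        warp/noise augmentations emulate on real data.
        """
        base = cls(warp_aug_sigma=0.0, noise_aug_geom=0.0, noise_aug_func=0.0)
        return replace(base, **overrides)


@dataclass
class TrainState:
    """Mutable scheduler/optimizer bookkeeping."""

    epoch: int = 0
    lr: float = 1e-3
    best_val: float = math.inf
    best_epoch: int = -1
    since_improve: int = 0
    plateau_events: int = 0


def lr_at(state: TrainState, config: TrainConfig) -> float:
    """Learning rate for the state's epoch.

    Linear from ``lr_init`` down to ``lr_floor`` across the first
    ``linear_phase_epochs`` epochs; afterwards ``lr_floor`` cut by
    ``plateau_factor`` once per recorded plateau event.
    """
    e = state.epoch
    lp = config.linear_phase_epochs
    if e <= lp:
        return config.lr_init + (config.lr_floor - config.lr_init) * e / lp
    return config.lr_floor * config.plateau_factor**state.plateau_events


def register_validation(state: TrainState, val_loss: float, config: TrainConfig) -> bool:
    """Update plateau bookkeeping; returns True if this is a new best."""
    improved = val_loss < state.best_val
    if improved:
        state.best_val = val_loss
        state.best_epoch = state.epoch
        state.since_improve = 0
    else:
        state.since_improve += 1
        if (state.epoch > config.linear_phase_epochs
                and state.since_improve >= config.plateau_patience):
            state.plateau_events += 1
            state.since_improve = 0
    return improved


class Adam(object):
    """Adam with default moment parameters; only the lr is scheduled."""

    def __init__(self, params: list[Tensor], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 lr_scales: list[float] | None = None):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.lr_scales = lr_scales if lr_scales is not None else [1.0] * len(params)
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v, scale in zip(self.params, self.m, self.v, self.lr_scales):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= (lr * scale * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _aug_warp(shape: tuple[int, int], config: TrainConfig,
              rng: np.random.Generator, theta: np.ndarray) -> np.ndarray:
    """Random smooth displacement, metric sd = warp_aug_sigma cells.

    The longitude component is divided by sin(theta) so that the on-sphere
    (metric) displacement magnitude is statistically uniform across rows.
    """
    white = rng.standard_normal((2, *shape))
    u = gaussian_filter(white, sigma=(0, config.warp_aug_smooth, config.warp_aug_smooth),
                        mode=("constant", "nearest", "wrap"))
    sd = u.std()
    if sd > 0:
        u *= config.warp_aug_sigma / sd
    u[1] /= np.sin(theta)[:, None]
    return u


def augment_batch(batch: list[FeatureMap], config: TrainConfig,
                  rng: np.random.Generator) -> list[FeatureMap]:
    """Warp + noise augmentation; one shared warp per subject across channels."""
    from .deformation import warp_array

    if config.warp_aug_sigma == 0 and config.noise_aug_geom == 0 \
            and config.noise_aug_func == 0:
        return batch
    out = []
    for fm in batch:
        vals = fm.values
        if config.warp_aug_sigma > 0:
            u = _aug_warp(fm.grid.shape, config, rng, fm.grid.theta)
            vals = warp_array(vals, u)
        else:
            vals = vals.copy()
        for c, role in enumerate(fm.channel_roles):
            if not fm.valid_mask[c]:
                continue
            sd = config.noise_aug_geom if role == "geometric" else config.noise_aug_func
            if sd > 0:
                vals[c] = vals[c] + rng.normal(0.0, sd, fm.grid.shape)
        out.append(FeatureMap(fm.grid, vals, fm.channel_roles, fm.valid_mask.copy()))
    return out


@dataclass
class TrainResult:
    model: RegistrationModel
    history: pd.DataFrame
    state: TrainState
    best_state_arrays: dict = field(default_factory=dict)


def _batch_arrays(maps: list[FeatureMap], dtype) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    geom = np.stack([np.moveaxis(m.role_values("geometric"), 0, -1) for m in maps]).astype(dtype)
    func_idx = np.array(
        [i for i, m in enumerate(maps)
         if len(m.channels_with_role("functional")) > 0
         and bool(m.valid_mask[m.channels_with_role("functional")].all())],
        dtype=np.intp,
    )
    func = None
    if func_idx.size:
        func = np.stack(
            [np.moveaxis(maps[i].role_values("functional"), 0, -1) for i in func_idx]
        ).astype(dtype)
    return geom, func, func_idx


def _loss_on_maps(model: RegistrationModel, maps: list[FeatureMap],
                  weights: LossWeights, w_arr: np.ndarray,
                  config: TrainConfig) -> tuple[Tensor, LossReport]:
    geom, func, func_idx = _batch_arrays(maps, model.dtype)
    x = tensor(geom)
    v_j, v_g, v_f = model.forward_velocities(x)
    func_t = tensor(func) if func is not None else None
    atlas_func = model.atlas.functional if model.atlas.functional.shape[-1] else None
    return total_loss_tensors(
        x, func_t, func_idx, v_j, v_g, v_f,
        model.atlas.geometric, atlas_func, weights, w_arr, config.int_steps,
    )


def train(model: RegistrationModel, cohort, config: TrainConfig,
          loss_weights: LossWeights | None = None,
          log_stream=None) -> TrainResult:
    """Fit network weights and atlas to a cohort by Adam on the objective.

    ``cohort`` is a SyntheticCohort or any sequence of objects exposing a
    ``features`` FeatureMap (or FeatureMaps directly).  Subjects are
    standardized per channel before training.  The best-validation
    checkpoint is retained (and restored at the end when
    ``config.restore_best``).
    """
    subjects = list(getattr(cohort, "subjects", cohort))
    maps_all = [standardize(getattr(s, "features", s)) for s in subjects]
    n = len(maps_all)
    if n < config.batch_size:
        raise ValueError(f"cohort of {n} smaller than batch size {config.batch_size}")
    weights = loss_weights if loss_weights is not None else LossWeights()
    w_arr = distortion_weights(model.grid).w
    model.atlas.frozen = config.atlas_frozen

    ss = np.random.SeedSequence(config.seed)
    rng_data, rng_aug = (np.random.default_rng(s) for s in ss.spawn(2))

    n_val = int(round(config.val_fraction * n))
    perm = rng_data.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if train_idx.size < config.batch_size:
        raise ValueError("training split smaller than batch size")

    # the atlas is an image-valued parameter whose useful step size is much
    # larger than a conv weight's; Adam equalizes per-entry step magnitude,
    # so the template gets its own learning-rate scale
    params = model.parameters()
    n_net = len(model.network_parameters())
    scales = [1.0] * n_net + [config.atlas_lr_multiplier] * (len(params) - n_net)
    opt = Adam(params, lr_scales=scales)
    state = TrainState(lr=config.lr_init)
    rows = []
    best_arrays = model.state_arrays()
    best_arrays = {k: v.copy() for k, v in best_arrays.items()}

    for epoch in range(config.epochs):
        state.epoch = epoch
        lr = lr_at(state, config)
        state.lr = lr
        order = rng_data.permutation(train_idx)
        n_batches = len(order) // config.batch_size
        epoch_reports: list[LossReport] = []
        for b in range(n_batches):
            sel = order[b * config.batch_size:(b + 1) * config.batch_size]
            maps = augment_batch([maps_all[i] for i in sel], config, rng_aug)
            opt.zero_grad()
            total, report = _loss_on_maps(model, maps, weights, w_arr, config)
            if not math.isfinite(report.total):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} batch {b}: {report}"
                )
            total.backward()
            opt.step(lr)
            epoch_reports.append(report)

        if val_idx.size:
            _, val_report = _loss_on_maps(
                model, [maps_all[i] for i in val_idx], weights, w_arr, config
            )
            val_total = val_report.total
        else:
            val_total = float(np.mean([r.total for r in epoch_reports]))
        if register_validation(state, val_total, config):
            best_arrays = {k: v.copy() for k, v in model.state_arrays().items()}

        row = {"epoch": epoch, "lr": lr, "val_total": val_total,
               "train_total": float(np.mean([r.total for r in epoch_reports]))}
        for name in LossReport.COMPONENT_FIELDS:
            row[name] = float(np.mean([getattr(r, name) for r in epoch_reports]))
        row["n_func_observed"] = int(np.sum([r.n_func_observed for r in epoch_reports]))
        rows.append(row)
        if log_stream is not None:
            if epoch == 0:
                log_stream.write(",".join(row.keys()) + "\n")
            log_stream.write(",".join(f"{v:.8g}" if isinstance(v, float) else str(v)
                                      for v in row.values()) + "\n")
            log_stream.flush()

    if config.restore_best and best_arrays:
        model.load_state_arrays(best_arrays)
    return TrainResult(model=model, history=pd.DataFrame(rows), state=state,
                       best_state_arrays=best_arrays)
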