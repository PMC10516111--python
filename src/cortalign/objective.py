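"""Training objective: negative log-likelihood of the generative model.

Under the two-stage Gaussian observation model, each observed feature image
is a noisy warp of the (learned) atlas, so the data-fidelity terms reduce to
distortion-weighted mean squared errors; the deformation priors contribute
smoothness penalties on each displacement field and a centrality penalty on
the cohort-mean joint displacement (driving an unbiased atlas).  Similarity
is evaluated symmetrically in subject space (atlas warped forward) and atlas
space (subject warped back through the group inverse) and averaged, which
counteracts atlas drift during template learning.

Functional data are semi-supervised: subjects without functional maps simply
drop out of the functional similarity terms (masked mean); nothing else
changes.  The noise scale sigma is not estimated separately - the 1/(4 sigma^2)
likelihood factor is absorbed into the functional:geometric weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .autodiff import Tensor, expand_batch, take_batch, tensor
from .diffgeo import compose_disp, integrate, to_batch_disp, warp_channels
from .grid import FeatureMap, WeightMap

__all__ = [
    "LossWeights",
    "LossReport",
    "smoothness_penalty",
    "centrality_penalty",
    "similarity_loss",
    "total_loss",
    "total_loss_tensors",
]


@dataclass(frozen=True)
class LossWeights:
    """Hyperparameters of the objective.

    ``lambda_j`` weights smoothness of the joint (large, between-subject)
    deformation, ``lambda_g``/``lambda_f`` the small per-modality ones;
    ``alpha_j`` the centrality (unbiased-atlas) term; the similarity terms
    are mixed ``w_func : w_geom`` (must sum to 1).
    """

    lambda_j: float = 0.1
    lambda_g: float = 0.2
    lambda_f: float = 0.2
    alpha_j: float = 0.01
    w_func: float = 0.7
    w_geom: float = 0.3

    def __post_init__(self) -> None:
        for name in ("lambda_j", "lambda_g", "lambda_f", "alpha_j", "w_func", "w_geom"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if abs(self.w_func + self.w_geom - 1.0) > 1e-9:
            raise ValueError("w_func + w_geom must equal 1")


@dataclass
class LossReport:
    """Scalar breakdown of one objective evaluation.

    ``total`` equals the weighted recombination of the components:
    ``w_geom*(sim_geom_atlas+sim_geom_subject)/2
    + w_func*(sim_func_atlas+sim_func_subject)/2
    + smooth_j + smooth_g + smooth_f + central_j``
    (smoothness/centrality components already include their lambda/alpha).
    """

    total: float
    sim_geom_atlas: float
    sim_geom_subject: float
    sim_func_atlas: float
    sim_func_subject: float
    smooth_j: float
    smooth_g: float
    smooth_f: float
    central_j: float
    n_func_observed: int

    COMPONENT_FIELDS = (
        "sim_geom_atlas", "sim_geom_subject", "sim_func_atlas", "sim_func_subject",
        "smooth_j", "smooth_g", "smooth_f", "central_j",
    )

    def recombined_total(self, weights: LossWeights) -> float:
        return (
            weights.w_geom * (self.sim_geom_atlas + self.sim_geom_subject) / 2.0
            + weights.w_func * (self.sim_func_atlas + self.sim_func_subject) / 2.0
            + self.smooth_j + self.smooth_g + self.smooth_f + self.central_j
        )


# ------------------------------------------------------------------ tensor core


def _weighted_mse_t(a: Tensor, b: Tensor, w_arr: np.ndarray) -> Tensor:
    """Distortion-weighted MSE over cells, averaged over batch and channels."""
    bsz = a.shape[0]
    n_ch = a.shape[-1]
    d = a - b
    w = w_arr[None, :, :, None].astype(a.data.dtype)
    num = (d.sqr() * w).sum()
    den = float(w_arr.sum()) * bsz * n_ch
    return num * (1.0 / den)


def _smoothness_t(u: Tensor, lam: float, w_arr: np.ndarray) -> Tensor:
    """Distortion-weighted mean of squared forward differences of u.

    Longitude differences wrap; latitude differences are one-sided (defined
    on the first n_lat-1 rows).  Each squared difference is weighted by
    sin(theta) at its own cell, and the mean runs over all differences of
    both displacement components.
    """
    bsz, n_lat, _, _ = u.shape
    dtype = u.data.dtype
    dr = u[:, 1:, :, :] - u[:, :-1, :, :]
    dc = u.roll(-1, 2) - u
    w_r = w_arr[:-1, :][None, :, :, None].astype(dtype)
    w_c = w_arr[None, :, :, None].astype(dtype)
    num = (dr.sqr() * w_r).sum() + (dc.sqr() * w_c).sum()
    den = bsz * 2.0 * (float(w_arr[:-1].sum()) + float(w_arr.sum()))
    return num * (lam / den)


def _centrality_t(u: Tensor, alpha: float) -> Tensor:
    """alpha times the spatial mean of squares of the batch-mean displacement."""
    u_bar = u.mean(axis=0)
    return u_bar.sqr().mean() * alpha


def total_loss_tensors(
    geom_obs: Tensor,
    func_obs: Tensor | None,
    func_idx: np.ndarray,
    v_j: Tensor,
    v_g: Tensor,
    v_f: Tensor,
    atlas_geom: Tensor,
    atlas_func: Tensor | None,
    weights: LossWeights,
    w_arr: np.ndarray,
    int_steps: int = 7,
) -> tuple[Tensor, LossReport]:
    """Differentiable objective on a batch.

    Parameters
    ----------
    geom_obs : (B, H, W, Cg) observed (standardized) geometric images.
    func_obs : (n_func, H, W, Cf) functional images of the subjects listed in
        ``func_idx`` (positions within the batch), or None.
    v_j, v_g, v_f : (B, H, W, 2) stationary velocities per subject.
    atlas_geom, atlas_func : (1, H, W, C) learnable template channels.
    w_arr : (H, W) sin(theta) distortion weights.
    """
    bsz = geom_obs.shape[0]
    func_idx = np.asarray(func_idx, dtype=np.intp)
    n_func = int(func_idx.size)

    u_j = integrate(v_j, int_steps)
    u_g = integrate(v_g, int_steps)
    u_j_inv = integrate(-v_j, int_steps)
    u_g_inv = integrate(-v_g, int_steps)

    # subject-space geometric map: A(phi_j(phi_g(x)))
    psi_g = compose_disp(u_j, u_g)
    # its group inverse: phi_g^{-1}(phi_j^{-1}(x))
    psi_g_inv = compose_disp(u_g_inv, u_j_inv)

    atlas_g_b = expand_batch(atlas_geom, bsz)
    sim_geom_subject = _weighted_mse_t(warp_channels(atlas_g_b, psi_g), geom_obs, w_arr)
    sim_geom_atlas = _weighted_mse_t(warp_channels(geom_obs, psi_g_inv), atlas_g_b, w_arr)

    smooth_j = _smoothness_t(u_j, weights.lambda_j, w_arr)
    smooth_g = _smoothness_t(u_g, weights.lambda_g, w_arr)
    u_f = integrate(v_f, int_steps)
    smooth_f = _smoothness_t(u_f, weights.lambda_f, w_arr)
    central_j = _centrality_t(u_j, weights.alpha_j)

    if n_func > 0 and func_obs is not None and atlas_func is not None:
        v_f_sel = take_batch(v_f, func_idx)
        u_f_sel = take_batch(u_f, func_idx)
        u_f_inv = integrate(-v_f_sel, int_steps)
        u_j_sel = take_batch(u_j, func_idx)
        u_j_inv_sel = take_batch(u_j_inv, func_idx)
        psi_f = compose_disp(u_j_sel, u_f_sel)
        psi_f_inv = compose_disp(u_f_inv, u_j_inv_sel)
        atlas_f_b = expand_batch(atlas_func, n_func)
        sim_func_subject = _weighted_mse_t(warp_channels(atlas_f_b, psi_f), func_obs, w_arr)
        sim_func_atlas = _weighted_mse_t(warp_channels(func_obs, psi_f_inv), atlas_f_b, w_arr)
    else:
        sim_func_subject = tensor(0.0)
        sim_func_atlas = tensor(0.0)

    total = (
        (sim_geom_atlas + sim_geom_subject) * (weights.w_geom / 2.0)
        + (sim_func_atlas + sim_func_subject) * (weights.w_func / 2.0)
        + smooth_j + smooth_g + smooth_f + central_j
    )
    report = LossReport(
        total=total.item(),
        sim_geom_atlas=sim_geom_atlas.item(),
        sim_geom_subject=sim_geom_subject.item(),
        sim_func_atlas=sim_func_atlas.item(),
        sim_func_subject=sim_func_subject.item(),
        smooth_j=smooth_j.item(),
        smooth_g=smooth_g.item(),
        smooth_f=smooth_f.item(),
        central_j=central_j.item(),
        n_func_observed=n_func,
    )
    return total, report


# ------------------------------------------------------------- public numpy API


def _disp_array(u) -> np.ndarray:
    """Accept a DeformationField, VelocityField-like, or (2,H,W) array."""
    if hasattr(u, "u"):
        u = u.u
    elif hasattr(u, "v"):
        u = u.v
    u = np.asarray(u, dtype=float)
    if u.ndim != 3 or u.shape[0] != 2:
        raise ValueError("displacement must have shape (2, n_lat, n_lon)")
    if not np.all(np.isfinite(u)):
        raise ValueError("displacement must be finite")
    return u


def smoothness_penalty(u, lam: float, w: WeightMap) -> float:
    """lam times the distortion-weighted mean squared forward-difference gradient."""
    arr = to_batch_disp(_disp_array(u))
    return _smoothness_t(tensor(arr), lam, w.w).item()


def centrality_penalty(batch_displacements: Sequence, alpha: float) -> float:
    """alpha times the mean squared entry of the batch-mean displacement u-bar."""
    if len(batch_displacements) == 0:
        raise ValueError("centrality_penalty requires a nonempty batch")
    stack = np.stack([np.moveaxis(_disp_array(u), 0, -1) for u in batch_displacements])
    return _centrality_t(tensor(stack), alpha).item()


def similarity_loss(observed: FeatureMap, model_image: FeatureMap, w: WeightMap) -> float:
    """Distortion-weighted MSE over valid channels (channel-averaged)."""
    if observed.grid != model_image.grid:
        raise ValueError("grids must match")
    if observed.n_channels != model_image.n_channels:
        raise ValueError("channel counts must match")
    valid = observed.valid_mask & model_image.valid_mask
    if not valid.any():
        raise ValueError("no valid channels to compare")
    a = np.moveaxis(observed.values[valid], 0, -1)[None]
    b = np.moveaxis(model_image.values[valid], 0, -1)[None]
    return _weighted_mse_t(tensor(a), tensor(b), w.w).item()


def total_loss(
    subjects: Sequence[FeatureMap],
    fields: Sequence,
    atlas,
    weights: LossWeights,
    w: WeightMap,
    int_steps: int = 7,
) -> LossReport:
    """Evaluate the full objective on a batch (non-differentiable front end).

    ``fields`` holds one predicted-field object per subject exposing
    velocity attributes ``v_j``, ``v_g``, ``v_f`` (the inverse deformations
    needed for the atlas-space terms are obtained by exponentiating the
    negated velocities).  ``atlas`` exposes ``geometric_values`` and
    ``functional_values`` arrays of shape (C, H, W).
    """
    if len(subjects) == 0 or len(subjects) != len(fields):
        raise ValueError("one predicted-field set per subject required")

    def vel(f, name) -> np.ndarray:
        v = getattr(f, name)
        return to_batch_disp(np.asarray(v.v if hasattr(v, "v") else v, dtype=float))[0]

    v_j = tensor(np.stack([vel(f, "v_j") for f in fields]))
    v_g = tensor(np.stack([vel(f, "v_g") for f in fields]))
    v_f = tensor(np.stack([vel(f, "v_f") for f in fields]))

    geom = np.stack([np.moveaxis(s.role_values("geometric"), 0, -1) for s in subjects])
    func_idx = np.array(
        [i for i, s in enumerate(subjects)
         if len(s.channels_with_role("functional")) > 0
         and bool(s.valid_mask[s.channels_with_role("functional")].all())],
        dtype=np.intp,
    )
    func_obs = None
    if func_idx.size:
        func = np.stack(
            [np.moveaxis(subjects[i].role_values("functional"), 0, -1) for i in func_idx]
        )
        func_obs = tensor(func)

    ag = tensor(np.moveaxis(np.asarray(atlas.geometric_values, dtype=float), 0, -1)[None])
    af_arr = np.asarray(atlas.functional_values, dtype=float)
    af = tensor(np.moveaxis(af_arr, 0, -1)[None]) if af_arr.size else None

    _, report = total_loss_tensors(
        tensor(geom), func_obs, func_idx, v_j, v_g, v_f, ag, af, weights, w.w, int_steps
    )
    return report
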