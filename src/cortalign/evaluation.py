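"""Registration quality metrics.

Alignment quality is scored as the per-subject Pearson correlation between a
subject's map (warped into atlas space) and the across-subject group mean
map - the subject itself included in the mean - with sin(theta) distortion
weights applied as frequency weights.  Paired method comparisons use a
one-tailed Wilcoxon signed-rank test.  Regularity is the percentage of grid
locations with non-positive Jacobian determinant of the composed fields.
On synthetic cohorts the recovered deformations are additionally scored
against the generative ground truth as a distortion-weighted mean endpoint
error in grid cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deformation import (DeformationField, compose, negative_jacobian_fraction,
                          warp)
from .grid import FeatureMap, WeightMap, distortion_weights, standardize

__all__ = [
    "corr_to_group_mean",
    "pairwise_improvement",
    "signed_rank_onetailed",
    "deformation_recovery_error",
    "mean_negative_jacobian",
    "EvaluationReport",
    "evaluate_cohort",
]


def _weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Pearson r with frequency weights; nan when either side is constant."""
    wsum = w.sum()
    mx = (w * x).sum() / wsum
    my = (w * y).sum() / wsum
    cov = (w * (x - mx) * (y - my)).sum()
    vx = (w * (x - mx) ** 2).sum()
    vy = (w * (y - my) ** 2).sum()
    if vx <= 0 or vy <= 0 or not np.isfinite(vx * vy):
        return np.nan
    denom = np.sqrt(vx * vy)
    if denom < 1e-300:
        return np.nan
    return float(cov / denom)


def corr_to_group_mean(
    images: list[FeatureMap], channel: int = 0, weights: WeightMap | None = None
) -> np.ndarray:
    """Per-subject weighted Pearson r against the group mean map.

    The group mean includes the subject under evaluation (plain 1/N sum).
    Subjects whose map, or whose group mean, is constant under the weights
    are flagged with nan rather than silently zeroed.
    """
    if len(images) < 2:
        raise ValueError("need at least two subjects")
    grid = images[0].grid
    for im in images:
        if im.grid != grid:
            raise ValueError("all images must share a grid")
    w = (weights or distortion_weights(grid)).w.ravel()
    stack = np.stack([im.values[channel].ravel() for im in images])
    mean_map = stack.mean(axis=0)
    return np.array([_weighted_pearson(s, mean_map, w) for s in stack])


def pairwise_improvement(after, before) -> np.ndarray | pd.Series:
    """Delta_k = after_k - before_k for aligned subject lists.

    pandas Series inputs must carry identical indexes in identical order (a
    permuted subject order is an alignment error, not something to reindex
    silently).
    """
    if isinstance(after, pd.Series) or isinstance(before, pd.Series):
        after, before = pd.Series(after), pd.Series(before)
        if len(after) != len(before) or list(after.index) != list(before.index):
            raise ValueError("subject order of 'after' and 'before' must match")
        return after - before
    after = np.asarray(after, dtype=float)
    before = np.asarray(before, dtype=float)
    if after.shape != before.shape:
        raise ValueError("after/before must have matching length")
    return after - before


def signed_rank_onetailed(deltas_a, deltas_b) -> float:
    """One-tailed Wilcoxon signed-rank p-value for H1: a > b (paired).

    Zero differences are discarded.  For n <= 25 retained pairs the p-value
    is exact - the sign-flip permutation distribution of the positive-rank
    sum, computed by dynamic programming over (doubled, hence integer)
    midranks, which remains exact under ties.  Larger samples use the normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(deltas_a, dtype=float)
    b = np.asarray(deltas_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    if n <= 25:
        r2 = np.rint(2 * ranks).astype(int)
        total = r2.sum()
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: counts.size - r]
            counts = counts + shifted
        target = int(np.rint(2 * w_plus))
        return float(counts[target:].sum() / 2.0**n)
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    from scipy.stats import norm

    z = (w_plus - mean - 0.5) / np.sqrt(var)
    return float(norm.sf(z))


def deformation_recovery_error(
    predicted: DeformationField, true: DeformationField,
    weights: WeightMap | None = None,
) -> float:
    """Distortion-weighted mean endpoint error between two maps, in cells.

    The longitude component of the displacement difference is taken modulo
    the grid width (a map displaced by W-1 columns equals one displaced by
    -1 column on the periodic axis).
    """
    if predicted.grid != true.grid:
        raise ValueError("deformations must share a grid")
    n_lon = true.grid.n_lon
    d0 = predicted.u[0] - true.u[0]
    d1 = (predicted.u[1] - true.u[1] + n_lon / 2.0) % n_lon - n_lon / 2.0
    dist = np.sqrt(d0**2 + d1**2)
    w = (weights or distortion_weights(true.grid)).w
    return float((w * dist).sum() / w.sum())


def mean_negative_jacobian(fields: list[DeformationField]) -> float:
    """Mean percentage of folded locations over a list of deformations."""
    if not fields:
        raise ValueError("no deformation fields supplied")
    return float(np.mean([negative_jacobian_fraction(f) for f in fields]))


@dataclass
class EvaluationReport:
    """Per-subject registration metrics for one trained model on one cohort."""

    corr_geom_after: np.ndarray
    corr_geom_before: np.ndarray
    corr_func_after: np.ndarray  # nan where a subject has no functional map
    corr_func_before: np.ndarray
    neg_jacobian_pct: np.ndarray  # per subject, mean over both composed fields
    recovery_geom: np.ndarray | None  # synthetic cohorts only
    recovery_func: np.ndarray | None

    @property
    def improvement_geom(self) -> np.ndarray:
        return pairwise_improvement(self.corr_geom_after, self.corr_geom_before)

    @property
    def improvement_func(self) -> np.ndarray:
        return pairwise_improvement(self.corr_func_after, self.corr_func_before)

    @property
    def mean_neg_jacobian_pct(self) -> float:
        return float(np.mean(self.neg_jacobian_pct))

    def to_frame(self) -> pd.DataFrame:
        data = {
            "corr_geom_after": self.corr_geom_after,
            "corr_geom_before": self.corr_geom_before,
            "corr_func_after": self.corr_func_after,
            "corr_func_before": self.corr_func_before,
            "neg_jacobian_pct": self.neg_jacobian_pct,
        }
        if self.recovery_geom is not None:
            data["recovery_geom"] = self.recovery_geom
            data["recovery_func"] = self.recovery_func
        return pd.DataFrame(data)


def evaluate_cohort(model, cohort, int_steps: int = 7) -> EvaluationReport:
    """Register every subject to atlas space and score the alignment.

    Subjects are standardized, registered from their geometric channel only
    (semi-supervision contract), warped into atlas space through the inverse
    composed fields, and correlated against the group mean before/after.
    When the cohort carries generative ground truth, the predicted composed
    maps are also scored against the true ones.
    """
    subjects = list(getattr(cohort, "subjects", cohort))
    maps = [standardize(getattr(s, "features", s)) for s in subjects]
    has_truth = all(hasattr(s, "true_v_j") for s in subjects)

    geom_before, geom_after = [], []
    func_before, func_after = [], []
    neg_jac = []
    rec_g, rec_f = [], []
    func_rows = []
    for s, fm in zip(subjects, maps):
        pred = model.predict_fields(fm.select("geometric"), int_steps)
        psi_g = pred.composed_geom()
        psi_f = pred.composed_func()
        neg_jac.append(0.5 * (negative_jacobian_fraction(psi_g)
                              + negative_jacobian_fraction(psi_f)))
        inv_g = pred.composed_geom_inverse(int_steps)
        inv_f = pred.composed_func_inverse(int_steps)
        aligned = warp(fm, inv_g)
        geom_before.append(fm)
        geom_after.append(aligned)
        f_idx = fm.channels_with_role("functional")
        if f_idx.size and fm.valid_mask[f_idx].all():
            func_rows.append(len(geom_before) - 1)
            func_before.append(fm)
            func_after.append(warp(fm, inv_f))
        if has_truth:
            true_psi_g = compose(s.true_phi_j(int_steps),
                                 _integrate(s.true_v_g, int_steps))
            true_psi_f = compose(s.true_phi_j(int_steps),
                                 _integrate(s.true_v_f, int_steps))
            rec_g.append(deformation_recovery_error(psi_g, true_psi_g))
            rec_f.append(deformation_recovery_error(psi_f, true_psi_f))

    n = len(subjects)
    cga = corr_to_group_mean(geom_after, channel=0)
    cgb = corr_to_group_mean(geom_before, channel=0)
    cfa = np.full(n, np.nan)
    cfb = np.full(n, np.nan)
    if len(func_rows) >= 2:
        f_ch = int(maps[0].channels_with_role("functional")[0])
        cfa[func_rows] = corr_to_group_mean(func_after, channel=f_ch)
        cfb[func_rows] = corr_to_group_mean(func_before, channel=f_ch)
    return EvaluationReport(
        corr_geom_after=cga, corr_geom_before=cgb,
        corr_func_after=cfa, corr_func_before=cfb,
        neg_jacobian_pct=np.array(neg_jac),
        recovery_geom=np.array(rec_g) if has_truth else None,
        recovery_func=np.array(rec_f) if has_truth else None,
    )


def _integrate(v, n_steps):
    from .deformation import integrate_svf

    return integrate_svf(v, n_steps)
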