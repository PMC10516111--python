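# Methods

## The model

`cortalign` registers cortical surfaces on the sphere by jointly aligning
*geometry* (folding features such as sulcal depth or curvature) and
*function* (task-fMRI contrast maps), while simultaneously learning an
unbiased multi-channel atlas.  The generative view: an unknown atlas **A**
(geometric + functional channels) is warped per subject by a large joint
diffeomorphism φ_j — the between-subject variability shared by geometry and
function — producing a latent joint image; geometric and functional
observations then arise by two further, *small* per-modality
diffeomorphisms φ_g and φ_f, with additive Gaussian noise (sd σ) at both
stages.  Marginally each observed channel is the composed warp of the atlas
plus noise of variance 2σ² (the two stages add).

A convolutional encoder–decoder h(I_g) predicts three stationary velocity
fields (v_j, v_g, v_f) from the *geometric* image alone; each is
exponentiated by scaling-and-squaring into a diffeomorphism.  Functional
data are semi-supervised: they enter only the loss, never the network
input, so inference needs geometry only.

Minimizing the negative log posterior gives the training objective

    L = w_g/2 (L_geom^subj + L_geom^atlas) + w_f/2 (L_func^subj + L_func^atlas)
        + λ_j S(u_j) + λ_g S(u_g) + λ_f S(u_f) + α_j ‖ū_j‖²

where the similarity terms are sin(θ)-weighted mean squared errors, S(u) is
the distortion-weighted mean squared forward-difference gradient of a
displacement, and ū_j is the batch-mean joint displacement (centrality —
the unbiased-template prior).  Subject-space terms compare the atlas warped
by φ_j∘φ_g (image-action order) with the observation; atlas-space terms
warp the observation back through the group inverse exp(−v_g)∘exp(−v_j) and
compare with the atlas.  Evaluating in both spaces and averaging (factor
1/2) counteracts atlas drift.  The noise scale σ is not estimated; the
1/(4σ²) likelihood factor is absorbed into the modality mix w_f : w_g.

### Default hyperparameters

| parameter | default | meaning |
|---|---|---|
| λ_j | 0.1 | smoothness of the large joint deformation |
| λ_g, λ_f | 0.2 | smoothness of the small per-modality deformations |
| w_f : w_g | 0.7 : 0.3 | functional : geometric similarity mix |
| α_j | 0.01 | centrality (unbiased atlas) weight |
| encoder filters | 128, 256, 384, 512, 640 | 5-level encoder; symmetric decoder; final convs 64, 32 |
| batch size | 8 | |
| learning rate | 1e-3 → 1e-4 linearly over 500 epochs, then ×0.9 per 100 stagnant validation epochs | Adam, default moments |
| integration steps | 7 | scaling-and-squaring depth |
| augmentation | warp sd 4 cells (distortion-corrected), noise sd 1 (geometric) / 6 (functional) | real-data training |

α_j is not a published value; 0.01 keeps the centrality term roughly two
orders below the similarity terms at initialization, and the training tests
verify its qualitative effect (smaller batch-mean joint displacement than
α_j = 0) rather than a particular magnitude.

The atlas, initialized from unit Gaussian noise, is trained with a
learning-rate multiplier (default 10) relative to the convolution weights.
Adam equalizes per-entry step magnitudes, so with a shared rate an
image-valued parameter that must travel O(1) per cell within a few hundred
steps cannot converge; the multiplier is the standard remedy for learnable
template parameters and is exposed in `TrainConfig`.

## Spherical parameterization

Features live on a cell-centered latitude–longitude grid: θ_i = π(i+½)/n_lat,
φ_j = 2πj/n_lon.  Cell-centering excludes the exact poles, so sin(θ) > 0
everywhere and the area-distortion weights w ∝ sin(θ) (max-normalized) are
strictly positive.  All spatial averages — similarity terms, smoothness
terms, correlations, endpoint errors — use these weights, restoring the
spherical area measure that the equiangular grid distorts.  Scattered
per-vertex data are resampled by inverse-great-circle-distance interpolation
over the k = 3 nearest vertices (exact hits take the vertex value); the
longitude seam is implicit because neighbor search runs in 3-D.  Each
feature channel is standardized per subject: median subtracted, divided by
the standard deviation (floored at 1e-6 so constant channels map to zero).

Deformations live on this 2-D grid in grid-cell units (component 0 = rows/
latitude, 1 = columns/longitude).  Sampling wraps in longitude and clamps at
the first/last row; no cross-pole wrapping is attempted.  This is a known
approximation near the poles, where the sin(θ) weights are smallest; the
synthetic velocity sampler additionally tapers fields by sin(θ) so simulated
deformations vanish toward the poles (cross-pole translation is not a motion
the spherical model represents).

## Numerics

* **Integration.**  exp(v) by scaling-and-squaring: u ← v/2^K, then K = 7
  self-compositions.  Inverses are exp(−v).  Composition and warping use
  bilinear interpolation with the wrap/clamp convention above.
* **Jacobians.**  Central differences of x ↦ x + u(x) with periodic
  longitude differences taken on the displacement (avoiding the seam jump)
  and one-sided differences at the first/last row; the regularity metric is
  the percentage of cells with det ≤ 0.
* **Gradient operator in the smoothness prior.**  First-order forward
  differences, wrapped in longitude, one-sided (defined on n_lat−1 rows) in
  latitude; each squared difference is weighted by sin(θ) at its own cell.
* **Tolerances.**  The operator test tolerances (1e-2 against a 1024-step
  Euler flow, 1e-4 associativity, etc.) are bilinear-interpolation-limited:
  they hold for fields whose curvature is resolved by the grid, and the
  tests pick grid/smoothness combinations accordingly.
* **Differentiation.**  Training gradients flow through a small tape-based
  reverse-mode autodiff over numpy arrays (convolutions as BLAS products on
  im2col buffers, fused numba kernels for bilinear pulls).  Every operator's
  adjoint is verified against central finite differences in the test suite.
* **Dual implementation guard.**  The public numpy objective and the
  differentiable training objective are the same code path (the numpy front
  end wraps arrays in constant tensors), so the loss reported during
  training is exactly the documented objective.

## The synthetic cohort generator

The simulator draws cohorts from the generative model itself, so every
recovery experiment has exact ground truth:

* **Atlas.**  Geometric channel: a banded sinusoidal folding pattern —
  a median-subtracted sum of incommensurate harmonics
  (sin 4θ·cos 3φ + 0.6 sin 3θ·cos(2φ+1) + 0.4 sin 5θ·cos(5φ+2.1)).
  The angular frequencies are deliberately mixed so that no longitudinal
  rotation maps the pattern onto itself: with a rotationally symmetric
  pattern the learned template can settle in a rotated frame while the
  (unpenalized-at-constant) modality fields absorb the shift, making
  ground-truth recovery ill-posed.  Functional channel:
  smooth positive blobs (t-map-like) of width 4 cells placed on the n = 6
  strongest folding ridges, then displaced longitudinally by `func_offset`
  (default 5 cells).  The offset makes the optimal functional alignment
  genuinely different from the geometric one — exactly the discrepancy the
  separate φ_g/φ_f fields exist to capture.
* **Deformations.**  Velocities are Gaussian white noise smoothed to a
  6-cell length scale, tapered by sin(θ), and rescaled to a peak speed:
  3.0 cells for the joint field (large between-subject variability), 0.8
  for the modality fields (small within-subject discrepancies).
* **Noise.**  Additive Gaussian noise, sd 0.25 per stage, at both the joint
  and the observation stage.
* **Centering.**  With `centered` (default), joint velocities are drawn in
  antithetic ±v pairs, so the cohort-mean joint *velocity* is exactly zero
  and the grand-mean joint displacement is tiny (second-order); an odd
  trailing subject receives v_j = 0.
* **Semi-supervision.**  `func_fraction` marks a rounded share of subjects
  as lacking functional maps.

What it does *not* emulate: real folding geometry and its spatial
statistics, BOLD acquisition and GLM estimation, inter-subject variation in
feature amplitude, rigid misalignment, or any geometry–function coupling
beyond the shared joint deformation (the per-subject modality fields are
independent of geometry by construction).  Passing recovery tests therefore
demonstrates that the estimator recovers the model it assumes — not
real-data performance.

## Reference experiment and scale choices

The reference study trains the desk-scale network (published filters ÷ 8,
yielding encoder [16, 32, 48, 64, 80]) on a 64×128 grid with 20 subjects
(cohort seed 7) for 200 epochs, and evaluates on 10 fresh subjects (seed 8).
These sizes keep the full train-and-evaluate cycle within minutes on one
CPU while preserving every structural element of the method (three fields,
dual-space loss, atlas learning, semi-supervision).

Augmentation is disabled for the synthetic reference experiments: the
random warps and the 1/6-sd noise augmentations emulate acquisition and
population variability on real data, which the generative simulator already
supplies at matched levels.  `TrainConfig()` keeps the published
augmentation defaults for real-data training; `TrainConfig.reference()`
is the synthetic-study variant.

Validation uses a held-out 20% split scored without augmentation; the
best-validation checkpoint is retained and restored after training.

## Known limitations

* Latitude clamping makes deformation algebra inexact within a cell or two
  of the poles; sin(θ) weighting suppresses, but does not eliminate, the
  effect in reported metrics.
* The 2-D parameterization is not intrinsically spherical: velocities are
  Euclidean on the grid, with no vector transport across the seam or poles.
* The tied-field ablation and recovery comparisons are made on the training
  cohort at a reduced epoch budget; they test ordering (separate beats
  tied), not converged effect sizes.
* Correlation metrics are computed on the parameterized grid, not resampled
  surface vertices.
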