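"""Canonical desk-scale experiment configuration.

One place defines the reference synthetic study: a 64x128 grid, 20 training
subjects simulated with joint amplitude 3.0 cells, per-modality amplitude
0.8 cells and per-stage noise sd 0.25 (cohort seed 7), a held-out set of 10
subjects (seed 8), the desk-scale network (published filter counts divided
by 8) and 200 training epochs with the published optimization
hyperparameters.  Tests and the reproduction script both import from here
so they exercise identical conditions.
"""

from __future__ import annotations

from dataclasses import replace

from .grid import make_grid
from .network import NetworkConfig, RegistrationModel
from .objective import LossWeights
from .synthetic import GenerativeConfig, SyntheticCohort, make_cohort
from .training import TrainConfig, TrainResult, train

__all__ = ["REFERENCE_GENERATIVE", "HELD_OUT_SEED", "reference_cohort",
           "held_out_cohort", "desk_model", "train_reference"]

REFERENCE_GENERATIVE = GenerativeConfig(
    n_lat=64, n_lon=128, n_subjects=20,
    joint_amplitude=3.0, modality_amplitude=0.8, sigma_noise=0.25, seed=7,
)
HELD_OUT_SEED = 8
DESK_SCALE_FACTOR = 8
REFERENCE_EPOCHS = 200


def reference_cohort(**overrides) -> SyntheticCohort:
    cfg = replace(REFERENCE_GENERATIVE, **overrides) if overrides else REFERENCE_GENERATIVE
    return make_cohort(cfg)


def held_out_cohort(n_subjects: int = 10, seed: int = HELD_OUT_SEED) -> SyntheticCohort:
    return make_cohort(replace(REFERENCE_GENERATIVE, n_subjects=n_subjects, seed=seed))


def desk_model(seed: int = 0, tie_modality_fields: bool = False) -> RegistrationModel:
    cfg = NetworkConfig.desk_scale(DESK_SCALE_FACTOR,
                                   tie_modality_fields=tie_modality_fields)
    grid = make_grid(REFERENCE_GENERATIVE.n_lat, REFERENCE_GENERATIVE.n_lon)
    return RegistrationModel(cfg, grid, n_geom_channels=1, n_func_channels=1, seed=seed)


def train_reference(
    cohort: SyntheticCohort | None = None,
    epochs: int = REFERENCE_EPOCHS,
    model_seed: int = 0,
    train_seed: int = 0,
    tie_modality_fields: bool = False,
    loss_weights: LossWeights | None = None,
    **train_overrides,
) -> tuple[RegistrationModel, TrainResult]:
    """Run the reference desk-scale training and return model + history."""
    cohort = cohort if cohort is not None else reference_cohort()
    model = desk_model(seed=model_seed, tie_modality_fields=tie_modality_fields)
    cfg = TrainConfig.reference(epochs=epochs, seed=train_seed, **train_overrides)
    result = train(model, cohort, cfg, loss_weights=loss_weights)
    return model, result
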