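"""Model / Results front end for joint geometry-function registration.

``JointSphericalRegistration`` bundles a cohort with the architecture, loss
and optimization settings; ``fit()`` runs the semi-supervised training loop
and returns a ``RegistrationResults`` carrying the trained network, the
learned atlas, the loss history and evaluation helpers, in the spirit of the
model/results split used by statistical modelling packages.

Example
-------
>>> from cortalign import GenerativeConfig, make_cohort
>>> from cortalign.model import JointSphericalRegistration
>>> cohort = make_cohort(GenerativeConfig(n_subjects=10, seed=7))
>>> model = JointSphericalRegistration(cohort, scale_factor=8, seed=0)
>>> res = model.fit(epochs=50)          # doctest: +SKIP
>>> print(res.summary())                # doctest: +SKIP
"""

from __future__ import annotations

import pandas as pd

from .evaluation import EvaluationReport, evaluate_cohort
from .grid import FUNCTIONAL, GEOMETRIC, FeatureMap, standardize
from .network import NetworkConfig, PredictedFields, RegistrationModel
from .objective import LossWeights
from .training import TrainConfig, TrainResult, train

__all__ = ["JointSphericalRegistration", "RegistrationResults"]


class JointSphericalRegistration:
    """Joint registration + atlas-learning model over a cohort of subjects.

    Parameters
    ----------
    cohort
        A ``SyntheticCohort`` or sequence of subjects / FeatureMaps.
    net_config
        Architecture; defaults to the full-scale network, or a desk-scale
        variant when ``scale_factor`` is given.
    loss_weights, train_config
        Objective and optimization hyperparameters.
    """

    def __init__(self, cohort, net_config: NetworkConfig | None = None,
                 loss_weights: LossWeights | None = None,
                 train_config: TrainConfig | None = None,
                 scale_factor: int | None = None, seed: int = 0):
        self.cohort = cohort
        subjects = list(getattr(cohort, "subjects", cohort))
        if not subjects:
            raise ValueError("empty cohort")
        fm: FeatureMap = getattr(subjects[0], "features", subjects[0])
        self.grid = fm.grid
        self.n_geom = len(fm.channels_with_role(GEOMETRIC))
        self.n_func = len(fm.channels_with_role(FUNCTIONAL))
        if net_config is None:
            net_config = (NetworkConfig.desk_scale(scale_factor)
                          if scale_factor else NetworkConfig())
        self.net_config = net_config
        self.loss_weights = loss_weights or LossWeights()
        self.train_config = train_config or TrainConfig()
        self.seed = seed
        self.network = RegistrationModel(
            net_config, self.grid, self.n_geom, self.n_func, seed=seed
        )

    @classmethod
    def from_container(cls, path, **kwargs) -> "JointSphericalRegistration":
        from .io import read_cohort

        return cls(read_cohort(path), **kwargs)

    def fit(self, epochs: int | None = None, log_stream=None) -> "RegistrationResults":
        cfg = self.train_config
        if epochs is not None:
            from dataclasses import replace

            cfg = replace(cfg, epochs=epochs)
        result = train(self.network, self.cohort, cfg,
                       loss_weights=self.loss_weights, log_stream=log_stream)
        return RegistrationResults(self, result)


class RegistrationResults:
    """Fit results: trained network, learned atlas, history, diagnostics."""

    def __init__(self, model: JointSphericalRegistration, result: TrainResult):
        self.model = model
        self.network = result.model
        self.history: pd.DataFrame = result.history
        self.state = result.state

    # ------------------------------------------------------------- estimates
    @property
    def atlas(self) -> FeatureMap:
        """The learned multi-channel atlas as a FeatureMap."""
        return self.network.atlas.as_feature_map()

    @property
    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.network.parameters()))

    def predict(self, geom: FeatureMap, standardized: bool = False) -> PredictedFields:
        """Predicted velocity/deformation fields for one subject's geometry."""
        fm = geom if standardized else standardize(geom)
        return self.network.predict_fields(fm.select(GEOMETRIC))

    def evaluate(self, cohort=None) -> EvaluationReport:
        """Registration metrics on a cohort (training cohort by default)."""
        return evaluate_cohort(self.network, cohort or self.model.cohort,
                               self.network.config.int_steps)

    def save(self, path) -> None:
        self.network.save(path)

    # --------------------------------------------------------------- summary
    def summary(self) -> str:
        h = self.history
        last = h.iloc[-1]
        lines = [
            "Joint Spherical Registration Results",
            "=" * 52,
            f"{'Grid':<28}{self.model.grid.n_lat} x {self.model.grid.n_lon}",
            f"{'Subjects':<28}{len(list(getattr(self.model.cohort, 'subjects', self.model.cohort)))}",
            f"{'Channels (geom/func)':<28}{self.model.n_geom} / {self.model.n_func}",
            f"{'Trainable parameters':<28}{self.n_params}",
            f"{'Epochs':<28}{len(h)}",
            f"{'Best val. loss':<28}{self.state.best_val:.6f} (epoch {self.state.best_epoch})",
            f"{'Final train loss':<28}{last['train_total']:.6f}",
            "-" * 52,
            "Final loss components",
        ]
        for name in ("sim_geom_subject", "sim_geom_atlas", "sim_func_subject",
                     "sim_func_atlas", "smooth_j", "smooth_g", "smooth_f",
                     "central_j"):
            lines.append(f"  {name:<26}{last[name]:.6f}")
        lines.append("=" * 52)
        return "\n".join(lines)
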