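"""Encoder-decoder registration network with a learnable multi-channel atlas.

The network consumes the parameterized *geometric* image only and emits
three stationary velocity fields: a joint field capturing the large
between-subject deformation, plus two small per-modality fields for
geometry and function.  Functional data never enter the forward pass - they
appear only in the training loss - so inference requires geometry alone.

The atlas (geometric + functional template channels) is part of the
trainable parameter set, initialized from seeded Gaussian noise and learned
jointly with the network unless frozen (fixed-atlas ablation).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import deformation as df
from .autodiff import Tensor, concat, conv2d, leaky_relu, maxpool2, parameter, tensor, upsample2
from .grid import FUNCTIONAL, GEOMETRIC, FeatureMap, SphericalGrid, make_grid

__all__ = ["NetworkConfig", "AtlasParameters", "RegistrationModel",
           "PredictedFields", "build_model"]

#: std of the velocity-head weight init; keeps the untrained model near identity
HEAD_INIT_STD = 1e-5


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    The defaults are the full-scale architecture (5-level encoder with
    [128, 256, 384, 512, 640] filters, symmetric decoder, two final
    convolutions with [64, 32] filters, leaky-rectifier activations).
    ``desk_scale`` divides every filter count for small-grid experiments.
    """

    encoder_filters: tuple[int, ...] = (128, 256, 384, 512, 640)
    decoder_filters: tuple[int, ...] | None = None
    final_conv_filters: tuple[int, ...] = (64, 32)
    activation_slope: float = 0.2
    velocity_scale: float = 1.0
    kernel_size: int = 3
    int_steps: int = df.DEFAULT_INT_STEPS
    tie_modality_fields: bool = False

    def __post_init__(self) -> None:
        dec = self.decoder_filters
        if dec is None:
            dec = tuple(reversed(self.encoder_filters[:-1]))
            object.__setattr__(self, "decoder_filters", dec)
        if len(dec) != len(self.encoder_filters) - 1:
            raise ValueError("decoder must mirror the encoder (one level fewer)")
        if any(f <= 0 for f in (*self.encoder_filters, *dec, *self.final_conv_filters)):
            raise ValueError("filter counts must be positive")

    @property
    def depth(self) -> int:
        return len(self.encoder_filters)

    @property
    def pool_factor(self) -> int:
        """Grid dimensions must be divisible by this (2 per pooling stage)."""
        return 2 ** (self.depth - 1)

    @classmethod
    def desk_scale(cls, factor: int = 8, **overrides) -> "NetworkConfig":
        """Full architecture with every filter count divided by `factor`."""
        base = cls()
        return cls(
            encoder_filters=tuple(max(2, f // factor) for f in base.encoder_filters),
            final_conv_filters=tuple(max(2, f // factor) for f in base.final_conv_filters),
            **overrides,
        )


@dataclass
class AtlasParameters:
    """Learnable template channels on the grid."""

    grid: SphericalGrid
    geometric: Tensor  # (1, n_lat, n_lon, n_geom)
    functional: Tensor  # (1, n_lat, n_lon, n_func); may have 0 channels
    frozen: bool = False

    @classmethod
    def random(cls, grid: SphericalGrid, n_geom: int, n_func: int,
               rng: np.random.Generator, std: float = 1.0,
               dtype=np.float32) -> "AtlasParameters":
        g = parameter(rng.normal(0.0, std, (1, grid.n_lat, grid.n_lon, n_geom)).astype(dtype))
        f = parameter(rng.normal(0.0, std, (1, grid.n_lat, grid.n_lon, n_func)).astype(dtype))
        return cls(grid=grid, geometric=g, functional=f)

    @property
    def geometric_values(self) -> np.ndarray:
        """(n_geom, n_lat, n_lon) numpy view of the geometric channels."""
        return np.moveaxis(self.geometric.data[0], -1, 0)

    @property
    def functional_values(self) -> np.ndarray:
        return np.moveaxis(self.functional.data[0], -1, 0)

    def as_feature_map(self) -> FeatureMap:
        vals = np.concatenate(
            [self.geometric_values.astype(float), self.functional_values.astype(float)]
        )
        roles = (GEOMETRIC,) * self.geometric.shape[-1] + (FUNCTIONAL,) * self.functional.shape[-1]
        return FeatureMap(self.grid, vals, roles)

    def trainable(self) -> list[Tensor]:
        return [] if self.frozen else [self.geometric, self.functional]


@dataclass
class PredictedFields:
    """The three velocities and their integrated deformations for one subject."""

    v_j: df.VelocityField
    v_g: df.VelocityField
    v_f: df.VelocityField
    phi_j: df.DeformationField
    phi_g: df.DeformationField
    phi_f: df.DeformationField

    def __iter__(self):
        return iter((self.phi_j, self.phi_g, self.phi_f))

    def composed_geom(self) -> df.DeformationField:
        """Map pulling the atlas into subject space through phi_j then phi_g."""
        return df.compose(self.phi_j, self.phi_g)

    def composed_func(self) -> df.DeformationField:
        return df.compose(self.phi_j, self.phi_f)

    def composed_geom_inverse(self, n_steps: int = df.DEFAULT_INT_STEPS) -> df.DeformationField:
        """Inverse composed map (subject -> atlas space), via exp of -v."""
        return df.compose(df.invert(self.v_g, n_steps), df.invert(self.v_j, n_steps))

    def composed_func_inverse(self, n_steps: int = df.DEFAULT_INT_STEPS) -> df.DeformationField:
        return df.compose(df.invert(self.v_f, n_steps), df.invert(self.v_j, n_steps))


class RegistrationModel:
    """The registration network h(I_geom) -> (v_j, v_g, v_f) plus its atlas."""

    def __init__(self, config: NetworkConfig, grid: SphericalGrid,
                 n_geom_channels: int, n_func_channels: int, seed: int = 0,
                 dtype=np.float32):
        if grid.n_lat % config.pool_factor or grid.n_lon % config.pool_factor:
            raise ValueError(
                f"grid {grid.n_lat}x{grid.n_lon} not divisible by {config.pool_factor} "
                f"(depth-{config.depth} encoder)"
            )
        self.config = config
        self.grid = grid
        self.n_geom_channels = int(n_geom_channels)
        self.n_func_channels = int(n_func_channels)
        self.seed = int(seed)
        self.dtype = dtype
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        k = config.kernel_size

        def conv_params(cin: int, cout: int, std: float | None = None):
            std = np.sqrt(2.0 / (k * k * cin)) if std is None else std
            w = parameter(rng.normal(0.0, std, (k, k, cin, cout)).astype(dtype))
            b = parameter(np.zeros(cout, dtype=dtype))
            return w, b

        self.enc: list[tuple[Tensor, Tensor]] = []
        cin = self.n_geom_channels
        for f in config.encoder_filters:
            self.enc.append(conv_params(cin, f))
            cin = f
        self.dec: list[tuple[Tensor, Tensor]] = []
        skips = list(config.encoder_filters[:-1])
        for f in config.decoder_filters:
            self.dec.append(conv_params(cin + skips.pop(), f))
            cin = f
        self.final: list[tuple[Tensor, Tensor]] = []
        for f in config.final_conv_filters:
            self.final.append(conv_params(cin, f))
            cin = f
        self.heads: list[tuple[Tensor, Tensor]] = [
            conv_params(cin, 2, std=HEAD_INIT_STD) for _ in range(3)
        ]
        self.atlas = AtlasParameters.random(
            grid, self.n_geom_channels, self.n_func_channels, rng, dtype=dtype
        )

    # ------------------------------------------------------------------ params
    def network_parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for w, b in (*self.enc, *self.dec, *self.final, *self.heads):
            out.extend((w, b))
        return out

    def parameters(self) -> list[Tensor]:
        return self.network_parameters() + self.atlas.trainable()

    # ----------------------------------------------------------------- forward
    def forward_velocities(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """Batched forward pass: (B, H, W, n_geom) -> three (B, H, W, 2)."""
        slope = self.config.activation_slope
        h = x
        skips: list[Tensor] = []
        for i, (w, b) in enumerate(self.enc):
            h = leaky_relu(conv2d(h, w, b), slope)
            if i < len(self.enc) - 1:
                skips.append(h)
                h = maxpool2(h)
        for (w, b), skip in zip(self.dec, reversed(skips)):
            h = upsample2(h)
            h = concat([h, skip], axis=3)
            h = leaky_relu(conv2d(h, w, b), slope)
        for w, b in self.final:
            h = leaky_relu(conv2d(h, w, b), slope)
        vs = [conv2d(h, w, b) * self.config.velocity_scale for w, b in self.heads]
        v_j, v_g, v_f = vs
        if self.config.tie_modality_fields:
            v_f = v_g
        return v_j, v_g, v_f

    def predict_fields(self, geom: FeatureMap, int_steps: int | None = None) -> PredictedFields:
        """Velocities and integrated deformations for one subject.

        The input must carry geometric channels only; feeding functional
        channels into the network path violates the semi-supervision
        contract and raises.
        """
        if any(r != GEOMETRIC for r in geom.channel_roles):
            raise ValueError(
                "predict_fields consumes geometric channels only; functional "
                "data must not enter the network"
            )
        if geom.grid != self.grid:
            raise ValueError("feature map grid does not match model grid")
        if geom.n_channels != self.n_geom_channels:
            raise ValueError("geometric channel count mismatch")
        steps = self.config.int_steps if int_steps is None else int_steps
        x = tensor(np.moveaxis(geom.values, 0, -1)[None].astype(self.dtype))
        vj_t, vg_t, vf_t = self.forward_velocities(x)

        def unpack(t: Tensor) -> df.VelocityField:
            return df.VelocityField(self.grid, np.moveaxis(t.data[0].astype(float), -1, 0))

        v_j, v_g, v_f = unpack(vj_t), unpack(vg_t), unpack(vf_t)
        return PredictedFields(
            v_j=v_j, v_g=v_g, v_f=v_f,
            phi_j=df.integrate_svf(v_j, steps),
            phi_g=df.integrate_svf(v_g, steps),
            phi_f=df.integrate_svf(v_f, steps),
        )

    # ------------------------------------------------------------- persistence
    def state_arrays(self) -> dict[str, np.ndarray]:
        arrs: dict[str, np.ndarray] = {}
        for i, (w, b) in enumerate((*self.enc, *self.dec, *self.final, *self.heads)):
            arrs[f"w{i}"] = w.data
            arrs[f"b{i}"] = b.data
        arrs["atlas_geom"] = self.atlas.geometric.data
        arrs["atlas_func"] = self.atlas.functional.data
        return arrs

    def load_state_arrays(self, arrs: dict[str, np.ndarray]) -> None:
        convs = (*self.enc, *self.dec, *self.final, *self.heads)
        for i, (w, b) in enumerate(convs):
            w.data = np.asarray(arrs[f"w{i}"], dtype=self.dtype)
            b.data = np.asarray(arrs[f"b{i}"], dtype=self.dtype)
        self.atlas.geometric.data = np.asarray(arrs["atlas_geom"], dtype=self.dtype)
        self.atlas.functional.data = np.asarray(arrs["atlas_func"], dtype=self.dtype)

    def save(self, path) -> None:
        """Checkpoint weights + atlas + config to an .npz file."""
        meta = dict(
            config=asdict(self.config), n_lat=self.grid.n_lat, n_lon=self.grid.n_lon,
            n_geom=self.n_geom_channels, n_func=self.n_func_channels, seed=self.seed,
        )
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.state_arrays())

    @classmethod
    def load(cls, path) -> "RegistrationModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            arrs = {k: z[k] for k in z.files if k != "__meta__"}
        cfg_dict = meta["config"]
        for key in ("encoder_filters", "decoder_filters", "final_conv_filters"):
            if cfg_dict.get(key) is not None:
                cfg_dict[key] = tuple(cfg_dict[key])
        cfg = NetworkConfig(**cfg_dict)
        model = cls(cfg, make_grid(meta["n_lat"], meta["n_lon"]),
                    meta["n_geom"], meta["n_func"], seed=meta["seed"])
        model.load_state_arrays(arrs)
        return model


def build_model(config: NetworkConfig, grid: SphericalGrid, n_geom_channels: int,
                n_func_channels: int, seed: int = 0) -> RegistrationModel:
    """Construct a seeded registration model (atlas initialized from noise)."""
    return RegistrationModel(config, grid, n_geom_channels, n_func_channels, seed=seed)
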