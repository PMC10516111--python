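"""File formats: the internal HDF5 container and surface-file readers.

Container layout::

    /grid/theta, /grid/phi          sampling angles (radians)
    /features/<name>                (channels, n_lat, n_lon) feature values
        attrs: channel_roles, valid_mask
    /deformations/<name>            (2, n_lat, n_lon) displacement
        attrs: units="grid-cells", axes="(lat,lon)"
    /truth/<subject>/v_{j,g,f}      generative ground-truth velocities

Displacement component 0 runs along the latitude (row) axis, component 1
along the periodic longitude (column) axis; units are grid cells.

FreeSurfer morph-data (curv/sulc), surface geometry and GIFTI overlays are
read through nibabel; this layer adds the consistency checks (unit-sphere
coordinates, matching vertex counts) and uniform error reporting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import h5py
import numpy as np

from .deformation import DeformationField, VelocityField
from .grid import FeatureMap, SphericalGrid
from .synthetic import GenerativeConfig, SyntheticCohort, SyntheticSubject

__all__ = [
    "write_feature_map", "read_feature_map", "write_cohort", "read_cohort",
    "write_deformation", "read_deformation",
    "read_morph_data", "write_morph_data", "read_sphere_geometry",
    "read_gifti_overlay", "write_manifest", "ConfigError",
    "dataclass_from_mapping", "sha256_of",
]


class ConfigError(ValueError):
    """Malformed or unknown configuration keys."""


def dataclass_from_mapping(cls, mapping: dict, where: str = "config"):
    """Build a dataclass strictly: any unknown key is an error, not a typo sink."""
    if mapping is None:
        mapping = {}
    if not isinstance(mapping, dict):
        raise ConfigError(f"{where}: expected a mapping, got {type(mapping).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")
    try:
        return cls(**mapping)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


# ----------------------------------------------------------------- HDF5 layer


def _write_grid(h5: h5py.File, grid: SphericalGrid) -> None:
    g = h5.require_group("grid")
    for name, data in (("theta", grid.theta), ("phi", grid.phi)):
        if name in g:
            del g[name]
        g.create_dataset(name, data=data)


def _read_grid(h5: h5py.File) -> SphericalGrid:
    theta = np.asarray(h5["grid/theta"])
    phi = np.asarray(h5["grid/phi"])
    return SphericalGrid(n_lat=theta.size, n_lon=phi.size, theta=theta, phi=phi)


def _put_feature(h5: h5py.File, name: str, fm: FeatureMap) -> None:
    grp = h5.require_group("features")
    if name in grp:
        del grp[name]
    ds = grp.create_dataset(name, data=fm.values)
    ds.attrs["channel_roles"] = [r.encode() for r in fm.channel_roles]
    ds.attrs["valid_mask"] = fm.valid_mask.astype(np.uint8)


def _get_feature(h5: h5py.File, name: str, grid: SphericalGrid) -> FeatureMap:
    ds = h5["features"][name]
    roles = tuple(
        r.decode() if isinstance(r, bytes) else str(r) for r in ds.attrs["channel_roles"]
    )
    mask = np.asarray(ds.attrs["valid_mask"], dtype=bool)
    return FeatureMap(grid, np.asarray(ds), roles, mask)


def write_feature_map(path, fm: FeatureMap, name: str = "features") -> None:
    with h5py.File(path, "a") as h5:
        _write_grid(h5, fm.grid)
        _put_feature(h5, name, fm)


def read_feature_map(path, name: str = "features") -> FeatureMap:
    with h5py.File(path, "r") as h5:
        return _get_feature(h5, name, _read_grid(h5))


def write_deformation(path, phi: DeformationField, name: str) -> None:
    with h5py.File(path, "a") as h5:
        _write_grid(h5, phi.grid)
        grp = h5.require_group("deformations")
        if name in grp:
            del grp[name]
        ds = grp.create_dataset(name, data=phi.u)
        ds.attrs["units"] = "grid-cells"
        ds.attrs["axes"] = "(lat,lon)"


def read_deformation(path, name: str) -> DeformationField:
    with h5py.File(path, "r") as h5:
        grid = _read_grid(h5)
        return DeformationField(grid, np.asarray(h5["deformations"][name]))


def write_cohort(path, cohort: SyntheticCohort) -> None:
    """Full synthetic cohort: features, atlas and ground-truth velocities."""
    with h5py.File(path, "w") as h5:
        _write_grid(h5, cohort.atlas.grid)
        h5.attrs["generative_config"] = json.dumps(dataclasses.asdict(cohort.config))
        _put_feature(h5, "atlas", cohort.atlas)
        for i, s in enumerate(cohort.subjects):
            name = f"subj{i:04d}"
            _put_feature(h5, name, s.features)
            t = h5.require_group(f"truth/{name}")
            for key, vf in (("v_j", s.true_v_j), ("v_g", s.true_v_g), ("v_f", s.true_v_f)):
                t.create_dataset(key, data=vf.v)
            for key, arr in (("noise_j", s.noise_j), ("noise_g", s.noise_g),
                             ("noise_f", s.noise_f)):
                t.create_dataset(key, data=arr)


def read_cohort(path) -> SyntheticCohort:
    with h5py.File(path, "r") as h5:
        grid = _read_grid(h5)
        config = dataclass_from_mapping(
            GenerativeConfig, json.loads(h5.attrs["generative_config"]),
            "generative_config",
        )
        atlas = _get_feature(h5, "atlas", grid)
        subjects = []
        names = sorted(n for n in h5["features"] if n.startswith("subj"))
        for name in names:
            fm = _get_feature(h5, name, grid)
            t = h5[f"truth/{name}"]
            subjects.append(SyntheticSubject(
                features=fm,
                true_v_j=VelocityField(grid, np.asarray(t["v_j"])),
                true_v_g=VelocityField(grid, np.asarray(t["v_g"])),
                true_v_f=VelocityField(grid, np.asarray(t["v_f"])),
                noise_j=np.asarray(t["noise_j"]),
                noise_g=np.asarray(t["noise_g"]),
                noise_f=np.asarray(t["noise_f"]),
            ))
    return SyntheticCohort(config=config, atlas=atlas, subjects=subjects)


# ------------------------------------------------------------ surface formats


def read_morph_data(path, expected_n_vertices: int | None = None) -> np.ndarray:
    """Per-vertex scalars from a FreeSurfer morph-data (curv/sulc) file."""
    from nibabel.freesurfer.io import read_morph_data as _read

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        values = np.asarray(_read(str(path)), dtype=float)
    except Exception as exc:
        raise ValueError(f"not a readable morph-data file: {path}: {exc}") from exc
    if expected_n_vertices is not None and values.size != expected_n_vertices:
        raise ValueError(
            f"{path}: {values.size} values but surface has {expected_n_vertices} vertices"
        )
    return values


def write_morph_data(path, values: np.ndarray) -> None:
    from nibabel.freesurfer.io import write_morph_data as _write

    _write(str(path), np.asarray(values, dtype=np.float32))


def read_sphere_geometry(path, tol: float = 1e-3) -> np.ndarray:
    """Unit-sphere vertex coordinates from a FreeSurfer surface file.

    FreeSurfer spheres are stored at radius ~100 mm; coordinates are
    rescaled to the unit sphere after checking they are spherical to `tol`
    relative spread.
    """
    from nibabel.freesurfer.io import read_geometry

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        coords, _faces = read_geometry(str(path))
    except Exception as exc:
        raise ValueError(f"not a readable surface file: {path}: {exc}") from exc
    coords = np.asarray(coords, dtype=float)
    norms = np.linalg.norm(coords, axis=1)
    radius = norms.mean()
    if radius == 0 or np.abs(norms / radius - 1.0).max() > tol:
        raise ValueError(f"{path}: surface is not spherical within tol {tol}")
    return coords / norms[:, None]


def read_gifti_overlay(path, expected_n_vertices: int | None = None) -> np.ndarray:
    """Per-vertex values from a GIFTI functional overlay (first data array)."""
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        values = np.asarray(img.agg_data(), dtype=float)
    except Exception as exc:
        raise ValueError(f"not a readable GIFTI overlay: {path}: {exc}") from exc
    if values.ndim > 1:
        values = values.reshape(values.shape[0], -1)[:, 0]
    if expected_n_vertices is not None and values.size != expected_n_vertices:
        raise ValueError(
            f"{path}: {values.size} values but surface has {expected_n_vertices} vertices"
        )
    return values


# ------------------------------------------------------------------ manifests


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(run_dir, configs: dict, seeds: dict, inputs: dict) -> Path:
    """Record everything needed to reproduce a run, before it starts."""
    from . import __version__

    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "configs": configs,
        "seeds": seeds,
        "inputs": {str(k): {"path": str(v), "sha256": sha256_of(v)}
                   for k, v in inputs.items()},
    }
    out = run_dir / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2))
    return out
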