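"""Synthetic dataset generation with reproducible manifests.

These fixtures stand in for experimental data: trajectory sets from the
chaotic system, pattern ensembles from the Turing model and radius
measurements from the colony model.  Every dataset is written together with
a JSON manifest recording the generating parameters, sizes and seeds;
re-running generation from the same spec is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .errors import ValidationError
from .forward_models import (
    ParameterVector,
    TuringGrid,
    TuringSolverConfig,
    colony_radii,
    observe_radius,
    sample_attractor,
    simulate_turing_ensemble,
)

__all__ = ["FixtureSpec", "generate_fixture", "regenerate_from_manifest"]

_KINDS = {"trajectory", "patterns", "radius"}


@dataclass(frozen=True)
class FixtureSpec:
    """Which synthetic dataset to emit, at which parameters and sizes."""

    kind: str
    theta: dict = field(default_factory=dict)
    size: int = 10
    seed: int = 0
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValidationError(f"kind must be one of {sorted(_KINDS)}")
        if self.size < 1:
            raise ValidationError("size must be at least 1")


def _trajectory_fixture(spec: FixtureSpec, out_dir: Path) -> list[str]:
    defaults = {"sigma": 10.0, "rho": 28.0, "beta": 8.0 / 3.0}
    defaults.update(spec.theta)
    theta = ParameterVector(tuple(defaults), np.array(list(defaults.values())))
    opts = {"dt": 0.5, "transient": 20.0, "epsilon": 1e-3, **spec.options}
    traj = sample_attractor(
        theta,
        n_points=spec.size,
        dt=opts["dt"],
        transient=opts["transient"],
        epsilon=opts["epsilon"],
        seed=spec.seed,
    )
    path = out_dir / "trajectory.csv"
    traj.to_csv(path, component_names=["x", "y", "z"])
    return [path.name]


def _pattern_fixture(spec: FixtureSpec, out_dir: Path) -> list[str]:
    defaults = {"a": 0.1, "b": 0.9, "gamma": 1.0, "d_u": 1.0, "d_v": 40.0}
    defaults.update(spec.theta)
    theta = ParameterVector(tuple(defaults), np.array(list(defaults.values())))
    opts = {
        "grid_n": 64,
        "grid_length": 50.0,
        "ic_amplitude": 0.01,
        "dt": 0.15,
        "t_int": 1000.0,
        **spec.options,
    }
    grid = TuringGrid((int(opts["grid_n"]),), opts["grid_length"])
    cfg = TuringSolverConfig(dt=opts["dt"], t_max=opts["t_int"])
    ens = simulate_turing_ensemble(theta, grid, spec.size, opts["ic_amplitude"], spec.seed, cfg)
    ens.save(out_dir / "patterns")
    return ["patterns.bin", "patterns.json"]


def _radius_fixture(spec: FixtureSpec, out_dir: Path) -> list[str]:
    defaults = {"alpha": 0.3, "sigma_k": 1.5, "sigma_s": 2.0, "sigma_o": 0.05}
    defaults.update(spec.theta)
    opts = {"t_max": 10.0, "r_max": 12.0, "n_r": 120, **spec.options}
    theta = ParameterVector(
        ("alpha", "sigma_k", "sigma_s"),
        np.array([defaults["alpha"], defaults["sigma_k"], defaults["sigma_s"]]),
    )
    times = np.linspace(0.0, opts["t_max"], spec.size)
    radii = colony_radii(theta, times, r_max=opts["r_max"], n_r=int(opts["n_r"]))
    meas = observe_radius(times, radii, defaults["sigma_o"], spec.seed)
    path = out_dir / "radius.csv"
    meas.to_csv(path)
    return [path.name]


def generate_fixture(spec: FixtureSpec, out_dir: str | Path, overwrite: bool = False) -> Path:
    """Write the dataset plus a ``manifest.json``; returns the manifest path.

    Refuses to overwrite an existing manifest unless ``overwrite`` is set.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace it")
    writer = {
        "trajectory": _trajectory_fixture,
        "patterns": _pattern_fixture,
        "radius": _radius_fixture,
    }[spec.kind]
    files = writer(spec, out_dir)
    manifest = {
        "spec": dataclasses.asdict(spec),
        "files": files,
        "version": __version__,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest_path


def regenerate_from_manifest(manifest_path: str | Path, out_dir: str | Path) -> Path:
    """Re-create a fixture from its manifest (byte-identical regeneration)."""
    manifest = json.loads(Path(manifest_path).read_text())
    spec = FixtureSpec(**manifest["spec"])
    return generate_fixture(spec, out_dir, overwrite=True)
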