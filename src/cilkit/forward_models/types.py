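"""Core containers shared by the forward models.

The containers are thin, validated wrappers around NumPy arrays.  Tabular
data (trajectories, radius measurements) round-trips through comma-separated
text with a header row and ``time`` as the first column; spatial patterns are
stored as flat float64 binary blocks with a JSON sidecar describing shape and
provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from ..errors import ValidationError

__all__ = [
    "ParameterVector",
    "TrajectorySet",
    "PatternEnsemble",
    "ColonySolution",
    "RadiusMeasurements",
]


@dataclass(frozen=True)
class ParameterVector:
    """Named real parameters of a forward model.

    Components flagged ``log_scale`` store the natural logarithm of the
    positive physical parameter; :meth:`physical` undoes the transform.
    """

    names: tuple[str, ...]
    values: np.ndarray
    log_scale: tuple[bool, ...] = ()

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", tuple(self.names))
        log_scale = tuple(self.log_scale) if self.log_scale else (False,) * len(self.names)
        object.__setattr__(self, "log_scale", log_scale)
        if values.ndim != 1 or len(self.names) != values.size:
            raise ValidationError("names and values must have equal length")
        if len(log_scale) != values.size:
            raise ValidationError("log_scale flags must match the number of components")
        if not np.all(np.isfinite(values)):
            raise ValidationError("parameter values must be finite")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def physical(self) -> dict[str, float]:
        """Parameter values on their physical (positive) scale."""
        out = {}
        for name, value, is_log in zip(self.names, self.values, self.log_scale):
            out[name] = float(np.exp(value)) if is_log else float(value)
        return out

    def replace_values(self, values: np.ndarray) -> "ParameterVector":
        return replace(self, values=np.asarray(values, dtype=float))

    @classmethod
    def from_dict(cls, mapping: dict[str, float], log_scale: Sequence[str] = ()) -> "ParameterVector":
        names = tuple(mapping)
        flags = tuple(n in set(log_scale) for n in names)
        values = np.array([np.log(mapping[n]) if f else mapping[n] for n, f in zip(names, flags)])
        return cls(names, values, flags)


@dataclass(frozen=True)
class TrajectorySet:
    """States of one model run sampled at strictly increasing times."""

    times: np.ndarray
    states: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        states = np.atleast_2d(np.asarray(self.states, dtype=float))
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)
        if times.ndim != 1 or states.shape[0] != times.size:
            raise ValidationError("states must have one row per time point")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ValidationError("times must be strictly increasing")
        if not np.all(np.isfinite(states)):
            raise ValidationError("states must be finite")

    @property
    def n_points(self) -> int:
        return self.times.size

    @property
    def state_dim(self) -> int:
        return self.states.shape[1]

    def observed(self, component_mask: Sequence[bool] | None = None) -> np.ndarray:
        """State matrix restricted to observable components."""
        if component_mask is None:
            return self.states
        mask = np.asarray(component_mask, dtype=bool)
        if mask.size != self.state_dim:
            raise ValidationError("component_mask length must equal the state dimension")
        return self.states[:, mask]

    def to_csv(self, path: str | Path, component_names: Sequence[str] | None = None) -> None:
        names = list(component_names or [f"x{i}" for i in range(self.state_dim)])
        header = ",".join(["time"] + names)
        data = np.column_stack([self.times, self.states])
        np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrajectorySet":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(times=data[:, 0], states=data[:, 1:])


@dataclass(frozen=True)
class PatternEnsemble:
    """Independent spatial patterns on a fixed grid for one parameter vector.

    ``patterns`` has shape ``(n, n_components, *grid_shape)``; each pattern
    carries every model component and ``component_mask`` selects the observed
    ones (partial observation).
    """

    patterns: np.ndarray
    grid_shape: tuple[int, ...]
    component_names: tuple[str, ...] = ("u",)
    component_mask: tuple[bool, ...] | None = None
    normalised: bool = False
    cell_volume: float = 1.0
    stationary: tuple[bool, ...] | None = None

    def __post_init__(self):
        patterns = np.asarray(self.patterns, dtype=float)
        grid_shape = tuple(int(g) for g in self.grid_shape)
        n_comp = len(self.component_names)
        expected = (patterns.shape[0], n_comp) + grid_shape
        if patterns.shape != expected:
            raise ValidationError(
                f"patterns shape {patterns.shape} does not match (n, {n_comp}, *{grid_shape})"
            )
        if patterns.shape[0] < 1:
            raise ValidationError("ensemble must contain at least one pattern")
        if not np.all(np.isfinite(patterns)):
            raise ValidationError("pattern values must be finite")
        mask = self.component_mask
        if mask is not None and len(mask) != n_comp:
            raise ValidationError("component_mask length must equal number of components")
        object.__setattr__(self, "patterns", patterns)
        object.__setattr__(self, "grid_shape", grid_shape)
        object.__setattr__(self, "component_names", tuple(self.component_names))
        object.__setattr__(self, "component_mask", tuple(mask) if mask is not None else None)

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    def observed(self) -> np.ndarray:
        """Patterns restricted to observable components, shape (n, c_obs, *grid)."""
        if self.component_mask is None:
            return self.patterns
        mask = np.asarray(self.component_mask, dtype=bool)
        return self.patterns[:, mask]

    def normalise(self) -> "PatternEnsemble":
        """Rescale each pattern component to [0, 1] (emulates scaled data)."""
        pats = self.patterns.copy()
        flat = pats.reshape(pats.shape[0], pats.shape[1], -1)
        lo = flat.min(axis=2, keepdims=True)
        hi = flat.max(axis=2, keepdims=True)
        span = np.where(hi - lo > 0, hi - lo, 1.0)
        flat = (flat - lo) / span
        return replace(self, patterns=flat.reshape(pats.shape), normalised=True)

    def subset(self, indices: Sequence[int]) -> "PatternEnsemble":
        idx = np.asarray(indices, dtype=int)
        stat = None
        if self.stationary is not None:
            stat = tuple(self.stationary[i] for i in idx)
        return replace(self, patterns=self.patterns[idx], stationary=stat)

    @classmethod
    def concatenate(cls, members: Sequence["PatternEnsemble"]) -> "PatternEnsemble":
        first = members[0]
        pats = np.concatenate([m.patterns for m in members], axis=0)
        stat = None
        if all(m.stationary is not None for m in members):
            stat = tuple(s for m in members for s in m.stationary)
        return replace(first, patterns=pats, stationary=stat)

    def save(self, stem: str | Path) -> None:
        """Write a flat float64 block ``<stem>.bin`` plus a JSON sidecar."""
        stem = Path(stem)
        self.patterns.astype("<f8").tofile(stem.with_suffix(".bin"))
        sidecar = {
            "shape": list(self.patterns.shape),
            "grid_shape": list(self.grid_shape),
            "component_names": list(self.component_names),
            "component_mask": list(self.component_mask) if self.component_mask else None,
            "normalised": self.normalised,
            "cell_volume": self.cell_volume,
            "stationary": list(self.stationary) if self.stationary else None,
            "dtype": "<f8",
        }
        stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")

    @classmethod
    def load(cls, stem: str | Path) -> "PatternEnsemble":
        stem = Path(stem)
        meta = json.loads(stem.with_suffix(".json").read_text())
        raw = np.fromfile(stem.with_suffix(".bin"), dtype=meta["dtype"])
        patterns = raw.reshape(meta["shape"])
        return cls(
            patterns=patterns,
            grid_shape=tuple(meta["grid_shape"]),
            component_names=tuple(meta["component_names"]),
            component_mask=tuple(meta["component_mask"]) if meta["component_mask"] else None,
            normalised=meta["normalised"],
            cell_volume=meta["cell_volume"],
            stationary=tuple(meta["stationary"]) if meta["stationary"] else None,
        )


@dataclass(frozen=True)
class ColonySolution:
    """Radial density p(r, t) of the nonlocal colony-growth model.

    ``p[i, j]`` is the radial density (mass per unit radius) at ``r_grid[i]``,
    ``t_grid[j]``; ``n`` is the underlying volumetric density in [0, 1] with
    p = 4 pi r^2 n.
    """

    r_grid: np.ndarray
    t_grid: np.ndarray
    p: np.ndarray
    n: np.ndarray
    overshoot: float = 0.0  # max excursion of n outside [0, 1]

    def __post_init__(self):
        r = np.asarray(self.r_grid, dtype=float)
        t = np.asarray(self.t_grid, dtype=float)
        object.__setattr__(self, "r_grid", r)
        object.__setattr__(self, "t_grid", t)
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        object.__setattr__(self, "n", np.asarray(self.n, dtype=float))
        if self.p.shape != (r.size, t.size):
            raise ValidationError("p must have shape (n_r, n_t)")

    def mass(self) -> np.ndarray:
        """Total colony mass per output time (trapezoidal quadrature)."""
        return np.trapezoid(self.p, self.r_grid, axis=0)


@dataclass(frozen=True)
class RadiusMeasurements:
    """Observed colony radii at increasing times, optionally with the truth."""

    times: np.ndarray
    observed: np.ndarray
    true_radii: np.ndarray | None = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        observed = np.asarray(self.observed, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "observed", observed)
        if self.true_radii is not None:
            object.__setattr__(self, "true_radii", np.asarray(self.true_radii, dtype=float))
        if times.shape != observed.shape:
            raise ValidationError("times and observed radii must have equal length")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ValidationError("times must be strictly increasing")
        if not np.all(observed > 0):
            raise ValidationError("observed radii must be positive")

    def to_csv(self, path: str | Path) -> None:
        if self.true_radii is not None:
            header = "time,radius,true_radius"
            data = np.column_stack([self.times, self.observed, self.true_radii])
        else:
            header = "time,radius"
            data = np.column_stack([self.times, self.observed])
        np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "RadiusMeasurements":
        with open(path) as fh:
            header = fh.readline().strip().split(",")
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        true_radii = data[:, 2] if len(header) >= 3 else None
        return cls(times=data[:, 0], observed=data[:, 1], true_radii=true_radii)
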