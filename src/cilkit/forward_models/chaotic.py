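"""Chaotic ODE systems and their trajectory sampler.

Trajectories of a chaotic system with fixed parameters diverge pointwise
under tiny perturbations of the initial state yet share the attractor's
geometry — the intrinsic variability the correlation-integral likelihood
exploits.  The registry is pluggable; Lorenz-63 with the classical
parameters is the default system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from ..errors import DivergenceError, ValidationError
from .types import ParameterVector, TrajectorySet

__all__ = [
    "SolverConfig",
    "lorenz63_rhs",
    "lorenz63_default_theta",
    "lorenz63_equilibrium",
    "register_system",
    "get_system",
    "simulate_chaotic",
    "perturb_initial_state",
    "sample_attractor",
]


@dataclass(frozen=True)
class SolverConfig:
    """Adaptive ODE solver settings (SciPy ``solve_ivp``)."""

    method: str = "RK45"
    rtol: float = 1e-6
    atol: float = 1e-9
    max_step: float = np.inf


def lorenz63_rhs(t: float, x: np.ndarray, theta: ParameterVector) -> np.ndarray:
    sigma, rho, beta = (theta[n] for n in ("sigma", "rho", "beta"))
    return np.array(
        [
            sigma * (x[1] - x[0]),
            x[0] * (rho - x[2]) - x[1],
            x[0] * x[1] - beta * x[2],
        ]
    )


def lorenz63_default_theta() -> ParameterVector:
    """Classical chaotic parameter set (sigma=10, rho=28, beta=8/3)."""
    return ParameterVector(("sigma", "rho", "beta"), np.array([10.0, 28.0, 8.0 / 3.0]))


def lorenz63_equilibrium(theta: ParameterVector, branch: int = 1) -> np.ndarray:
    """Nontrivial fixed point C+/C- of the Lorenz vector field."""
    rho, beta = theta["rho"], theta["beta"]
    c = np.sqrt(beta * (rho - 1.0))
    return np.array([branch * c, branch * c, rho - 1.0])


_SYSTEMS: dict[str, Callable] = {"lorenz63": lorenz63_rhs}


def register_system(name: str, rhs: Callable) -> None:
    """Register an ODE right-hand side ``rhs(t, x, theta)`` under ``name``."""
    _SYSTEMS[name] = rhs


def get_system(name: str) -> Callable:
    try:
        return _SYSTEMS[name]
    except KeyError:
        raise ValidationError(f"unknown chaotic system {name!r}; known: {sorted(_SYSTEMS)}")


def simulate_chaotic(
    theta: ParameterVector,
    x0: np.ndarray,
    times: np.ndarray,
    solver_cfg: SolverConfig | None = None,
    system: str = "lorenz63",
) -> TrajectorySet:
    """Integrate the registered system and sample the state at ``times``.

    Deterministic given ``(theta, x0, solver_cfg)``.  Raises
    :class:`DivergenceError` naming the time of failure if the state blows up.
    """
    cfg = solver_cfg or SolverConfig()
    times = np.asarray(times, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    if times.size >= 2 and not np.all(np.diff(times) > 0):
        raise ValidationError("times must be strictly increasing")
    rhs = get_system(system)
    if times.size == 1:
        # no integration needed: single row equal to the initial state
        return TrajectorySet(times=times, states=x0[None, :])
    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        x0,
        t_eval=times,
        args=(theta,),
        method=cfg.method,
        rtol=cfg.rtol,
        atol=cfg.atol,
        max_step=cfg.max_step,
    )
    if not sol.success:
        raise DivergenceError(f"integration failed at t={sol.t[-1]:.6g}: {sol.message}", time=float(sol.t[-1]))
    states = sol.y.T
    if not np.all(np.isfinite(states)):
        bad = np.where(~np.all(np.isfinite(states), axis=1))[0][0]
        raise DivergenceError(f"non-finite state at t={times[bad]:.6g}", time=float(times[bad]))
    return TrajectorySet(times=times, states=states)


def perturb_initial_state(x0: np.ndarray, epsilon: float, seed: int) -> np.ndarray:
    """x0 + epsilon * xi, xi standard normal from a seeded generator."""
    if epsilon < 0:
        raise ValidationError("epsilon must be non-negative")
    x0 = np.asarray(x0, dtype=float)
    if epsilon == 0:
        return x0.copy()
    rng = np.random.default_rng(seed)
    return x0 + epsilon * rng.standard_normal(x0.shape)


def sample_attractor(
    theta: ParameterVector,
    n_points: int,
    dt: float,
    x0: np.ndarray | None = None,
    transient: float = 20.0,
    epsilon: float = 1e-3,
    seed: int = 0,
    solver_cfg: SolverConfig | None = None,
    system: str = "lorenz63",
) -> TrajectorySet:
    """One trajectory on the attractor after a transient, seeded perturbation.

    Convenience wrapper used to generate training/evaluation data for the
    correlation-integral likelihood: the initial state is perturbed with the
    seeded generator, a transient is discarded, and ``n_points`` states are
    sampled every ``dt`` time units.
    """
    if x0 is None:
        x0 = np.array([1.0, 1.0, 1.0])
    x0 = perturb_initial_state(np.asarray(x0, dtype=float), epsilon, seed)
    times = transient + dt * np.arange(n_points + 1)
    full = simulate_chaotic(theta, x0, np.concatenate([[0.0], times]), solver_cfg, system)
    # drop the initial point and the transient sample
    return TrajectorySet(times=full.times[2:], states=full.states[2:])
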