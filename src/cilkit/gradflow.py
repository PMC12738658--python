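"""Samplers from the gradient-flow viewpoint, plus a 1-D Fokker-Planck oracle.

The target density exp(-V)/Z is the stationary solution of the
Fokker-Planck equation d_t rho = div(grad rho + rho grad V), whose
Kullback-Leibler divergence to the target decays monotonically in time
(the Lyapunov property of the flow).  Three ways of realising the flow are
provided:

* unadjusted Langevin (Euler-Maruyama on dX = -grad V dt + sqrt(2) dB),
* Stein variational gradient descent, a deterministic interacting-particle
  system combining kernel-smoothed gradient descent with kernel-gradient
  repulsion,
* a conservative finite-volume solver for the 1-D Fokker-Planck equation
  itself, used as the reference against which the particle methods are
  checked.

Gradient-flow samplers here are wired to smooth analytic potentials; the
stochastic correlation-integral costs are sampled with the
Metropolis-family algorithms instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .errors import GradientFailureError, TimeStepError, ValidationError

__all__ = [
    "ParticleEnsemble",
    "KernelSpec",
    "DensityGrid1D",
    "grad_potential",
    "langevin_sample",
    "svgd_step",
    "svgd_sample",
    "fokker_planck_1d",
    "stationary_density",
    "kl_divergence_grids",
    "kl_decay_monitor",
]


@dataclass(frozen=True)
class ParticleEnsemble:
    """N equally weighted particle positions at a given pseudo-time."""

    positions: np.ndarray
    time: float = 0.0
    diverged: np.ndarray | None = None
    converged: bool = True

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "positions", pos)
        if self.diverged is None:
            object.__setattr__(self, "diverged", np.zeros(pos.shape[0], dtype=bool))

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def weights(self) -> np.ndarray:
        return np.full(self.n_particles, 1.0 / self.n_particles)


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian RBF kernel K(z) = exp(-|z|^2 / h).

    ``bandwidth`` is either a positive number h or the string ``"median"``
    for the median heuristic h = median(|z_ij|)^2 / log(N + 1), recomputed
    at every iteration.
    """

    family: str = "rbf"
    bandwidth: float | str = "median"

    def __post_init__(self):
        if self.family != "rbf":
            raise ValidationError(f"unknown kernel family {self.family!r}")
        if not isinstance(self.bandwidth, str) and self.bandwidth <= 0:
            raise ValidationError("kernel bandwidth must be positive")

    def resolve_bandwidth(self, positions: np.ndarray) -> float:
        if not isinstance(self.bandwidth, str):
            return float(self.bandwidth)
        if self.bandwidth != "median":
            raise ValidationError(f"unknown bandwidth rule {self.bandwidth!r}")
        n = positions.shape[0]
        if n < 2:
            return 1.0
        diff = positions[:, None, :] - positions[None, :, :]
        dist = np.sqrt(np.sum(diff**2, axis=-1))
        med = np.median(dist[np.triu_indices(n, k=1)])
        if med == 0:
            return 1.0
        return float(med**2 / np.log(n + 1.0))


@dataclass(frozen=True)
class DensityGrid1D:
    """Probability density on a uniform 1-D grid, trapezoid-normalised."""

    nodes: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        nodes = np.asarray(self.nodes, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "values", values)
        if nodes.shape != values.shape or nodes.ndim != 1:
            raise ValidationError("nodes and values must be 1-D arrays of equal length")
        h = np.diff(nodes)
        if not np.allclose(h, h[0]):
            raise ValidationError("grid must be uniform")
        if np.any(values < 0):
            raise ValidationError("density must be non-negative")
        mass = np.trapezoid(values, nodes)
        if abs(mass - 1.0) > 1e-8:
            raise ValidationError(f"density must integrate to 1 (got {mass:.3e})")

    @property
    def h(self) -> float:
        return float(self.nodes[1] - self.nodes[0])

    @classmethod
    def from_unnormalised(cls, nodes: np.ndarray, values: np.ndarray) -> "DensityGrid1D":
        values = np.asarray(values, dtype=float)
        mass = np.trapezoid(values, nodes)
        return cls(nodes=nodes, values=values / mass)


# ---------------------------------------------------------------------------
# gradients


def grad_potential(V: Callable, theta: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Gradient of a potential: analytic if ``V.grad`` exists, else central
    differences with relative step ``h``."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    analytic = getattr(V, "grad", None)
    if analytic is not None:
        return np.atleast_1d(np.asarray(analytic(theta), dtype=float))
    g = np.empty_like(theta)
    for i in range(theta.size):
        step = h * max(1.0, abs(theta[i]))
        plus, minus = theta.copy(), theta.copy()
        plus[i] += step
        minus[i] -= step
        vp, vm = V(plus), V(minus)
        if not (np.isfinite(vp) and np.isfinite(vm)):
            raise GradientFailureError(f"non-finite potential in stencil at component {i}")
        g[i] = (vp - vm) / (2.0 * step)
    return g


class AnalyticPotential:
    """Potential with a registered analytic gradient.

    ``grad`` maps a single point to its gradient; the optional
    ``grad_batch`` maps an (N, d) position matrix to an (N, d) gradient
    matrix and lets the particle samplers avoid per-particle Python loops.
    """

    def __init__(self, V: Callable, grad: Callable, grad_batch: Callable | None = None):
        self._V = V
        self.grad = grad
        if grad_batch is not None:
            self.grad_batch = grad_batch

    def __call__(self, theta):
        return self._V(theta)


def _batch_grad(V: Callable, positions: np.ndarray) -> np.ndarray:
    """Gradient of V at every row of ``positions``."""
    batch = getattr(V, "grad_batch", None)
    if batch is not None:
        return np.asarray(batch(positions), dtype=float)
    return np.array([grad_potential(V, p) for p in positions])


# ---------------------------------------------------------------------------
# Langevin


def langevin_sample(
    V: Callable,
    theta0_ensemble: np.ndarray,
    step_h: float,
    n_steps: int,
    seed: int,
    noise: bool = True,
) -> ParticleEnsemble:
    """Euler-Maruyama discretisation of the overdamped Langevin diffusion.

    X_{k+1} = X_k - h grad V(X_k) + sqrt(2 h) xi_k with independent standard
    normal increments per particle.  ``noise=False`` degenerates to plain
    gradient descent.  Particles reaching non-finite positions are frozen
    and flagged in ``diverged``.
    """
    if step_h <= 0:
        raise ValidationError("step size must be positive")
    pos = np.atleast_2d(np.asarray(theta0_ensemble, dtype=float)).copy()
    n, d = pos.shape
    rng = np.random.default_rng(seed)
    diverged = np.zeros(n, dtype=bool)
    for _ in range(n_steps):
        update = pos - step_h * _batch_grad(V, pos)
        if noise:
            update = update + np.sqrt(2.0 * step_h) * rng.standard_normal((n, d))
        bad = ~np.all(np.isfinite(update), axis=1)
        diverged |= bad
        update[bad] = pos[bad]  # freeze diverged particles
        pos = update
    if np.any(diverged):
        warnings.warn(f"{int(diverged.sum())} particle(s) diverged and were frozen", stacklevel=2)
    return ParticleEnsemble(positions=pos, time=step_h * n_steps, diverged=diverged)


# ---------------------------------------------------------------------------
# SVGD


def _rbf_kernel_terms(positions: np.ndarray, h: float):
    diff = positions[:, None, :] - positions[None, :, :]  # (i, j, d) = theta_i - theta_j
    sq = np.sum(diff**2, axis=-1)
    K = np.exp(-sq / h)
    gradK = -2.0 / h * diff * K[:, :, None]  # grad K evaluated at theta_i - theta_j
    return K, gradK


def svgd_step(
    ensemble: ParticleEnsemble,
    V: Callable,
    kernel: KernelSpec,
    dt: float,
) -> ParticleEnsemble:
    """One explicit-Euler step of the SVGD particle system.

    d theta_i / dt = -(1/N) sum_j grad K(theta_i - theta_j)
                     -(1/N) sum_j K(theta_i - theta_j) grad V(theta_j);
    the first sum is kernel repulsion between particles, the second a
    kernel-weighted gradient descent on the potential.
    """
    if dt <= 0:
        raise ValidationError("dt must be positive")
    pos = ensemble.positions
    n = pos.shape[0]
    h = kernel.resolve_bandwidth(pos)
    K, gradK = _rbf_kernel_terms(pos, h)
    gradV = _batch_grad(V, pos)
    velocity = -(gradK.sum(axis=1) + K @ gradV) / n
    return replace(ensemble, positions=pos + dt * velocity, time=ensemble.time + dt)


def svgd_sample(
    V: Callable,
    init_ensemble: ParticleEnsemble | np.ndarray,
    kernel: KernelSpec | None = None,
    dt: float = 0.1,
    n_steps: int = 2000,
    tol: float = 1e-6,
) -> ParticleEnsemble:
    """Iterate SVGD until the max particle displacement per step drops below
    ``tol`` or ``n_steps`` is reached; deterministic given the initial
    ensemble.  Non-convergence sets ``converged=False`` rather than raising.
    """
    kernel = kernel or KernelSpec()
    ens = (
        init_ensemble
        if isinstance(init_ensemble, ParticleEnsemble)
        else ParticleEnsemble(positions=init_ensemble)
    )
    for _ in range(n_steps):
        new = svgd_step(ens, V, kernel, dt)
        disp = np.max(np.abs(new.positions - ens.positions))
        ens = new
        if disp < tol:
            return replace(ens, converged=True)
    return replace(ens, converged=False)


# ---------------------------------------------------------------------------
# 1-D Fokker-Planck reference solver


def stationary_density(V: Callable, nodes: np.ndarray) -> DensityGrid1D:
    """Discretised target density exp(-V)/Z on the grid."""
    vals = np.exp(-np.array([float(V(np.array([x]))) for x in nodes]))
    return DensityGrid1D.from_unnormalised(nodes, vals)


def _bernoulli(w: np.ndarray) -> np.ndarray:
    """B(w) = w / (e^w - 1), the exponential-fitting flux weight."""
    out = np.empty_like(w)
    small = np.abs(w) < 1e-10
    out[small] = 1.0 - w[small] / 2.0
    ws = w[~small]
    out[~small] = ws / np.expm1(ws)
    return out


def _fp_generator(V: Callable, nodes: np.ndarray) -> np.ndarray:
    """Tridiagonal generator Q with d rho / dt = Q rho, no-flux boundaries.

    Fluxes use exponential fitting (Scharfetter-Gummel / Chang-Cooper
    weights), which makes the discrete density proportional to e^{-V}
    exactly stationary and conserves mass to round-off (columns of Q sum
    to zero).
    """
    n = nodes.size
    h = nodes[1] - nodes[0]
    Vv = np.array([float(V(np.array([x]))) for x in nodes])
    w = np.diff(Vv)  # V_{i+1} - V_i at interior faces
    Bp = _bernoulli(w)  # multiplies rho_i  (flux towards i+1)
    Bm = _bernoulli(-w)  # multiplies rho_{i+1}
    Q = np.zeros((n, n))
    inv_h2 = 1.0 / h**2
    for i in range(n - 1):
        # face between i and i+1: J = (Bp rho_i - Bm rho_{i+1}) / h^2
        Q[i, i] -= Bp[i] * inv_h2
        Q[i, i + 1] += Bm[i] * inv_h2
        Q[i + 1, i] += Bp[i] * inv_h2
        Q[i + 1, i + 1] -= Bm[i] * inv_h2
    return Q


def fokker_planck_1d(
    V: Callable,
    rho0: DensityGrid1D,
    dt: float,
    T: float,
    store_every: int = 1,
) -> tuple[np.ndarray, list[DensityGrid1D]]:
    """Evolve d_t rho = d_x (d_x rho + rho V') to time T, explicit Euler.

    Returns ``(times, densities)`` including the initial state.  The scheme
    is conservative (mass exact to round-off) and positivity-preserving
    under the CFL condition dt * max|Q_ii| <= 1; violation raises
    :class:`TimeStepError` with a suggested step.
    """
    Q = _fp_generator(V, rho0.nodes)
    max_diag = float(np.max(-np.diag(Q)))
    if dt * max_diag > 1.0:
        raise TimeStepError(
            f"dt={dt:g} violates the stability limit; use dt <= {0.9 / max_diag:.3e}",
            suggested_dt=0.9 / max_diag,
        )
    n_steps = int(np.round(T / dt))
    rho = rho0.values.copy()
    times = [0.0]
    out = [rho0]
    # node-based trapezoid mass: halve boundary node contributions
    for k in range(1, n_steps + 1):
        rho = rho + dt * (Q @ rho)
        if k % store_every == 0 or k == n_steps:
            times.append(k * dt)
            out.append(DensityGrid1D(nodes=rho0.nodes, values=np.maximum(rho, 0.0)))
    return np.array(times), out


def kl_divergence_grids(p: DensityGrid1D, q: DensityGrid1D) -> float:
    """Trapezoidal quadrature of the relative entropy Int p log(p/q).

    0 log 0 is treated as 0; p > 0 where q = 0 violates absolute continuity
    and returns +inf with a warning.
    """
    if not np.array_equal(p.nodes, q.nodes):
        raise ValidationError("densities must share the grid")
    pv, qv = p.values, q.values
    if np.any((pv > 0) & (qv == 0)):
        warnings.warn("absolute continuity violated: p > 0 where q = 0", stacklevel=2)
        return np.inf
    integrand = np.zeros_like(pv)
    mask = pv > 0
    integrand[mask] = pv[mask] * np.log(pv[mask] / qv[mask])
    return float(np.trapezoid(integrand, p.nodes))


def kl_decay_monitor(
    trajectory: tuple[np.ndarray, list[DensityGrid1D]],
    V: Callable,
    tol: float = 1e-8,
) -> np.ndarray:
    """KL(rho_t || rho_inf) per stored time of a Fokker-Planck trajectory.

    The relative entropy to the stationary density is the Lyapunov
    functional of the flow; a violation of monotone decay beyond ``tol``
    triggers a warning (it indicates a too-coarse discretisation).
    """
    times, densities = trajectory
    rho_inf = stationary_density(V, densities[0].nodes)
    kls = np.array([kl_divergence_grids(rho, rho_inf) for rho in densities])
    increases = np.diff(kls)
    if np.any(increases > tol):
        warnings.warn(
            f"KL divergence increased by up to {float(np.max(increases)):.3e}", stacklevel=2
        )
    return kls
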