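"""Classical Bayesian building blocks: Gaussian prior, Gaussian and
lognormal-multiplicative likelihoods, and the posterior potential V(theta).

All positive model parameters are handled on the log scale, so priors are
Gaussians on log-parameters and no positivity constraints are needed during
sampling.  Normalising constants are dropped everywhere except in the
colony likelihood, whose sigma_o-dependent normalisation must be retained
because the measurement error is itself estimated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .errors import CilkitError, ValidationError
from .forward_models.colony import ColonySolverConfig, colony_radii
from .forward_models.types import ParameterVector, RadiusMeasurements

__all__ = [
    "GaussianPrior",
    "PotentialSpec",
    "log_prior",
    "gaussian_loglik",
    "potential",
    "colony_loglik",
    "make_colony_potential",
    "mc_integrate",
]


@dataclass(frozen=True)
class GaussianPrior:
    """Gaussian prior N(m, Sigma_prior) on the (log-)parameter vector."""

    m: np.ndarray
    Sigma_prior: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.m, dtype=float)
        S = np.atleast_2d(np.asarray(self.Sigma_prior, dtype=float))
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "Sigma_prior", S)
        if S.shape != (m.size, m.size):
            raise ValidationError("prior covariance shape must match the mean")
        if not np.allclose(S, S.T):
            raise ValidationError("prior covariance must be symmetric")
        try:
            cho_factor(S)
        except np.linalg.LinAlgError:
            raise ValidationError("prior covariance must be positive definite")


@dataclass(frozen=True)
class PotentialSpec:
    """Ingredients of the posterior potential V(theta).

    ``forward_map`` maps a parameter vector to the model prediction in data
    space; ``Gamma`` is the observational noise covariance.
    """

    forward_map: Callable[[np.ndarray], np.ndarray]
    data: np.ndarray
    Gamma: np.ndarray
    prior: GaussianPrior

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        G = np.atleast_2d(np.asarray(self.Gamma, dtype=float))
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "Gamma", G)
        if G.shape != (data.size, data.size):
            raise ValidationError("noise covariance shape must match the data")
        if not np.allclose(G, G.T):
            raise ValidationError("noise covariance must be symmetric")


def _quad_form(residual: np.ndarray, cov: np.ndarray) -> float:
    residual = np.atleast_1d(np.asarray(residual, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if cov.shape != (residual.size, residual.size):
        raise ValidationError("covariance and residual dimensions disagree")
    return float(residual @ cho_solve(cho_factor(cov), residual))


def log_prior(theta: np.ndarray, prior: GaussianPrior) -> float:
    """Unnormalised Gaussian log-prior -1/2 |theta - m|^2_Sigma."""
    return -0.5 * _quad_form(np.asarray(theta, dtype=float) - prior.m, prior.Sigma_prior)


def gaussian_loglik(data: np.ndarray, prediction: np.ndarray, Gamma: np.ndarray) -> float:
    """Unnormalised Gaussian log-likelihood -1/2 |D - M(theta)|^2_Gamma."""
    d = np.asarray(data, dtype=float)
    pred = np.asarray(prediction, dtype=float)
    if d.shape != pred.shape:
        raise ValidationError("data and prediction shapes disagree")
    return -0.5 * _quad_form(d - pred, Gamma)


def potential(theta: np.ndarray, spec: PotentialSpec) -> float:
    """Posterior potential V = -log-likelihood - log-prior (up to constants).

    A forward-model failure maps to V = +inf (zero posterior mass) with a
    warning, so samplers survive proposals in non-physical regions.
    """
    try:
        prediction = spec.forward_map(np.asarray(theta, dtype=float))
    except CilkitError as exc:
        warnings.warn(f"forward model failed at theta={theta}: {exc}", stacklevel=2)
        return np.inf
    return -(gaussian_loglik(spec.data, prediction, spec.Gamma) + log_prior(theta, spec.prior))


def colony_loglik(
    meas: RadiusMeasurements,
    theta: ParameterVector,
    solver_cfg: ColonySolverConfig | None = None,
    r_max: float = 12.0,
    n_r: int = 120,
) -> float:
    """Lognormal-multiplicative log-likelihood of radius measurements.

    sum_i [ -log(sqrt(2 pi) sigma_o) - (log r_obs_i - log r_theta(t_i))^2 /
    (2 sigma_o^2) ] with r_theta from the colony solver; the normalisation
    is kept because sigma_o is an estimated parameter.  Solver failures give
    -inf with a warning.
    """
    phys = theta.physical()
    sigma_o = phys["sigma_o"]
    if sigma_o <= 0:
        raise ValidationError("sigma_o must be positive")
    try:
        r_model = colony_radii(theta, meas.times, r_max=r_max, n_r=n_r, solver_cfg=solver_cfg)
    except CilkitError as exc:
        warnings.warn(f"colony solver failed: {exc}", stacklevel=2)
        return -np.inf
    resid = np.log(meas.observed) - np.log(r_model)
    n = resid.size
    return float(-n * np.log(np.sqrt(2.0 * np.pi) * sigma_o) - np.sum(resid**2) / (2.0 * sigma_o**2))


def make_colony_potential(
    meas: RadiusMeasurements,
    prior: GaussianPrior,
    names: tuple[str, ...] = ("alpha", "sigma_k", "sigma_s", "sigma_o"),
    solver_cfg: ColonySolverConfig | None = None,
    r_max: float = 12.0,
    n_r: int = 120,
) -> Callable[[np.ndarray], float]:
    """Log-posterior (up to a constant) over log-parameters for MCMC.

    Returns a callable suitable as a sampler ``log_target``: it assembles a
    log-scale :class:`ParameterVector` from the raw vector, adds the colony
    log-likelihood and the Gaussian log-prior on the log-parameters.
    """
    flags = (True,) * len(names)

    def log_target(x: np.ndarray) -> float:
        theta = ParameterVector(names, np.asarray(x, dtype=float), flags)
        ll = colony_loglik(meas, theta, solver_cfg, r_max, n_r)
        return ll + log_prior(theta.values, prior)

    return log_target


def mc_integrate(f: Callable[[np.ndarray], float], n: int, seed: int, d: int = 1) -> float:
    """Plain Monte Carlo mean of f over the unit cube [0, 1]^d."""
    if n < 1:
        raise ValidationError("n must be at least 1")
    rng = np.random.default_rng(seed)
    x = rng.random((n, d))
    values = np.array([f(xi) for xi in x], dtype=float)
    if not np.all(np.isfinite(values)):
        bad = int(np.where(~np.isfinite(values))[0][0])
        raise ValidationError(f"non-finite integrand value at sample point {x[bad]}")
    return float(values.mean())
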