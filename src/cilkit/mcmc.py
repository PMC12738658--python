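"""Metropolis-family samplers targeting exp(log_target).

For classical Bayesian targets the log-target is the negative potential
-V(theta); for correlation-integral costs f(theta) the documented
convention is log_target = -f(theta)/2, which makes f play the role of a
(doubled) negative log-likelihood.

Stochastic targets (the CIL/SCIL costs) are re-evaluated at every proposal;
the value at the current state is cached from when it was accepted rather
than re-sampled.  Set ``refresh_current=True`` to re-evaluate the current
state each step instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol

import json
import numpy as np

from .errors import ValidationError

__all__ = [
    "Chain",
    "Proposal",
    "GaussianRandomWalk",
    "metropolis",
    "metropolis_hastings",
    "adaptive_metropolis",
    "AdaptConfig",
    "chain_diagnostics",
]


@dataclass
class Chain:
    """Ordered MCMC samples with log-target values and acceptance flags."""

    samples: np.ndarray
    log_target: np.ndarray
    accepted: np.ndarray
    seed: int
    proposal_cfg: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return self.samples.shape[0]

    @property
    def acceptance_rate(self) -> float:
        return float(np.mean(self.accepted))

    def to_csv(self, path: str | Path, names: list[str] | None = None) -> None:
        d = self.samples.shape[1]
        names = names or [f"theta{i}" for i in range(d)]
        header = ",".join(names + ["log_target", "accepted"])
        data = np.column_stack([self.samples, self.log_target, self.accepted.astype(float)])
        np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.17g")
        sidecar = {
            "seed": self.seed,
            "proposal_cfg": self.proposal_cfg,
            "acceptance_rate": self.acceptance_rate,
            "n_steps": self.n_steps,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")


class Proposal(Protocol):
    """Proposal distribution q(theta_new | theta_current)."""

    def sample(self, rng: np.random.Generator, current: np.ndarray) -> np.ndarray: ...

    def log_density(self, new: np.ndarray, given: np.ndarray) -> float: ...


@dataclass(frozen=True)
class GaussianRandomWalk:
    """Symmetric random walk N(current, s * Id); ``s`` is the variance."""

    s: float

    def sample(self, rng: np.random.Generator, current: np.ndarray) -> np.ndarray:
        return current + np.sqrt(self.s) * rng.standard_normal(current.shape)

    def log_density(self, new: np.ndarray, given: np.ndarray) -> float:
        r = np.asarray(new) - np.asarray(given)
        return float(-0.5 * np.sum(r**2) / self.s)


def _run_chain(
    log_target: Callable[[np.ndarray], float],
    theta0: np.ndarray,
    n_steps: int,
    seed: int,
    propose: Callable[[np.random.Generator, np.ndarray, int], np.ndarray],
    hastings_correction: Callable[[np.ndarray, np.ndarray], float] | None,
    refresh_current: bool,
    on_step: Callable[[int, np.ndarray], None] | None = None,
    proposal_cfg: dict | None = None,
) -> Chain:
    theta0 = np.atleast_1d(np.asarray(theta0, dtype=float))
    current_lp = float(log_target(theta0))
    if not np.isfinite(current_lp):
        raise ValidationError("log_target must be finite at the initial state")
    rng = np.random.default_rng(seed)
    d = theta0.size
    samples = np.empty((n_steps, d))
    lps = np.empty(n_steps)
    accepted = np.zeros(n_steps, dtype=bool)
    current = theta0.copy()
    for j in range(n_steps):
        candidate = propose(rng, current, j)
        cand_lp = float(log_target(candidate))
        if refresh_current:
            current_lp = float(log_target(current))
        log_ratio = cand_lp - current_lp
        if hastings_correction is not None:
            log_ratio += hastings_correction(current, candidate)
        if np.log(rng.random()) < log_ratio:
            current, current_lp = candidate, cand_lp
            accepted[j] = True
        samples[j] = current
        lps[j] = current_lp
        if on_step is not None:
            on_step(j, current)
    return Chain(samples, lps, accepted, seed, proposal_cfg or {})


def metropolis(
    log_target: Callable[[np.ndarray], float],
    theta0: np.ndarray,
    step_s: float,
    n_steps: int,
    seed: int,
    refresh_current: bool = False,
) -> Chain:
    """Random-walk Metropolis with proposal N(current, step_s * Id).

    Accepts with probability min(1, exp(log_target(candidate) -
    log_target(current))); the step variance ``step_s`` controls mixing.
    """
    if step_s <= 0:
        raise ValidationError("step_s must be positive")
    rw = GaussianRandomWalk(step_s)
    return _run_chain(
        log_target,
        theta0,
        n_steps,
        seed,
        propose=lambda rng, cur, j: rw.sample(rng, cur),
        hastings_correction=None,
        refresh_current=refresh_current,
        proposal_cfg={"type": "metropolis", "step_s": step_s},
    )


def metropolis_hastings(
    log_target: Callable[[np.ndarray], float],
    proposal: Proposal,
    theta0: np.ndarray,
    n_steps: int,
    seed: int,
    refresh_current: bool = False,
) -> Chain:
    """Metropolis-Hastings with an asymmetric proposal.

    Acceptance uses the standard correction
    min(1, exp(dlog_target + log q(current | candidate) - log q(candidate | current))),
    which cancels for symmetric proposals.
    """

    def correction(current: np.ndarray, candidate: np.ndarray) -> float:
        return proposal.log_density(current, candidate) - proposal.log_density(candidate, current)

    return _run_chain(
        log_target,
        theta0,
        n_steps,
        seed,
        propose=lambda rng, cur, j: proposal.sample(rng, cur),
        hastings_correction=correction,
        refresh_current=refresh_current,
        proposal_cfg={"type": "metropolis_hastings", "proposal": type(proposal).__name__},
    )


@dataclass(frozen=True)
class AdaptConfig:
    """Adaptive-Metropolis settings.

    Before step ``t0`` the proposal covariance is ``cov0`` (default
    ``(0.1^2 / d) Id``); afterwards it tracks ``sd * cov(history) +
    sd * epsilon * Id`` with the usual dimension-dependent scale
    sd = 2.38^2 / d.
    """

    t0: int = 200
    sd: float | None = None  # default 2.38^2 / d
    epsilon: float = 1e-8
    cov0: np.ndarray | None = None


class _RunningMoments:
    """Recursive mean/covariance over the chain history."""

    def __init__(self, d: int):
        self.n = 0
        self.mean = np.zeros(d)
        self._m2 = np.zeros((d, d))

    def push(self, x: np.ndarray) -> None:
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self._m2 += np.outer(delta, x - self.mean)

    @property
    def cov(self) -> np.ndarray:
        if self.n < 2:
            return np.zeros_like(self._m2)
        return self._m2 / (self.n - 1)


def adaptive_metropolis(
    log_target: Callable[[np.ndarray], float],
    theta0: np.ndarray,
    n_steps: int,
    adapt_cfg: AdaptConfig | None = None,
    seed: int = 0,
    refresh_current: bool = False,
) -> Chain:
    """Random-walk Metropolis whose proposal covariance tracks the history.

    Implements the classical adaptation rule: after an initial period
    ``t0`` with a fixed covariance, proposals are drawn from
    N(current, sd * cov(history) + sd * epsilon * Id), where the history
    covariance is maintained recursively.
    """
    cfg = adapt_cfg or AdaptConfig()
    theta0 = np.atleast_1d(np.asarray(theta0, dtype=float))
    d = theta0.size
    if cfg.t0 < 1:
        raise ValidationError("adaptation start t0 must be at least 1")
    sd = cfg.sd if cfg.sd is not None else 2.38**2 / d
    cov0 = cfg.cov0 if cfg.cov0 is not None else (0.1**2 / d) * np.eye(d)
    cov0 = np.atleast_2d(np.asarray(cov0, dtype=float))
    chol0 = np.linalg.cholesky(cov0)
    moments = _RunningMoments(d)
    moments.push(theta0)
    state = {"chol": chol0}

    def propose(rng: np.random.Generator, current: np.ndarray, j: int) -> np.ndarray:
        if j >= cfg.t0:
            cov = sd * moments.cov + sd * cfg.epsilon * np.eye(d)
            state["chol"] = np.linalg.cholesky(cov)
        return current + state["chol"] @ rng.standard_normal(d)

    def on_step(j: int, current: np.ndarray) -> None:
        moments.push(current)

    return _run_chain(
        log_target,
        theta0,
        n_steps,
        seed,
        propose=propose,
        hastings_correction=None,
        refresh_current=refresh_current,
        on_step=on_step,
        proposal_cfg={"type": "adaptive_metropolis", "t0": cfg.t0, "sd": sd, "epsilon": cfg.epsilon},
    )


def _ess_1d(x: np.ndarray) -> float:
    """Effective sample size via the autocorrelation sum truncated at the
    first negative pair of consecutive autocorrelations."""
    n = x.size
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        return 1.0
    acf = np.correlate(x, x, mode="full")[n - 1 :] / (n * var)
    s = 0.0
    for k in range(1, n - 1, 2):
        pair = acf[k] + acf[k + 1]
        if pair < 0:
            break
        s += pair
    tau = 1.0 + 2.0 * s
    return float(min(n, max(1.0, n / tau)))


def chain_diagnostics(chain: Chain, burn_in_fraction: float = 0.3) -> dict:
    """Acceptance rate, per-dimension ESS, posterior mean and covariance."""
    if not 0 <= burn_in_fraction < 1:
        raise ValidationError("burn_in_fraction must lie in [0, 1)")
    burn = int(burn_in_fraction * chain.n_steps)
    if burn >= chain.n_steps:
        raise ValidationError("burn-in removes the whole chain")
    post = chain.samples[burn:]
    ess = np.array([_ess_1d(post[:, i]) for i in range(post.shape[1])])
    degenerate = bool(np.any(post.std(axis=0) == 0))
    return {
        "acceptance_rate": chain.acceptance_rate,
        "ess": ess,
        "posterior_mean": post.mean(axis=0),
        "posterior_cov": np.atleast_2d(np.cov(post, rowvar=False)),
        "n_post": post.shape[0],
        "degenerate": degenerate,
    }
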