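"""Self-contained reproduction experiments at the package's study conditions.

Each function runs one complete experiment from scratch — simulating its own
synthetic data, building the likelihood or sampler under test and measuring
the outcome — and returns a small dict of computed numbers.  The test suite
asserts on these dicts; the reproduction script prints them.

Problem sizes are fixed here as the package's reference conditions:

* chi^2 calibration of the pattern CIL cost uses 2-D Schnakenberg patterns
  (32 x 32 cells, box length 40) with N = 10 patterns per subset and
  n_ens = 40 training subsets (780 realisations for M = 10 bins).  Large
  subset counts matter: with few subsets the estimated covariance is both
  noisy and biased low (all subset pairs share members), which visibly
  inflates the Mahalanobis cost above its chi^2(M) limit.
* the chaotic variant uses one long Lorenz-63 trajectory cut into
  n_ens = 60 blocks of N = 50 states sampled every 0.5 time units.
* posterior recovery for the colony model uses 10 radius measurements on
  [0, 10] at theta* = (alpha 0.3, sigma_k 1.5, sigma_s 2.0, sigma_o 0.05)
  and 5000-step adaptive-Metropolis chains (2000 burn-in); shorter chains
  estimate the central-interval endpoints too tightly and undercover.
"""

from __future__ import annotations

import warnings

import numpy as np

from .bayes import GaussianPrior, make_colony_potential
from .cil import (
    chi2_calibration,
    cil_cost_at_parameter,
    estimate_statistics,
    partition_items,
    pattern_items,
    scil_cost,
    scil_statistics,
    trajectory_items,
)
from .forward_models import (
    ParameterVector,
    TuringGrid,
    TuringSolverConfig,
    colony_radii,
    colony_radius,
    lorenz63_default_theta,
    observe_radius,
    sample_attractor,
    schnakenberg_default_theta,
    simulate_turing_ensemble,
)
from .forward_models.types import ColonySolution
from .gradflow import (
    AnalyticPotential,
    DensityGrid1D,
    KernelSpec,
    ParticleEnsemble,
    fokker_planck_1d,
    kl_decay_monitor,
    langevin_sample,
    stationary_density,
    svgd_sample,
    svgd_step,
)
from .mcmc import AdaptConfig, adaptive_metropolis, _RunningMoments

__all__ = [
    "colony_radius_closed_form",
    "turing_chi2_experiment",
    "lorenz_chi2_experiment",
    "colony_recovery_experiment",
    "ula_variance_experiment",
    "fokker_planck_lyapunov_experiment",
    "svgd_experiment",
    "oracle_equivalences",
    "scil_single_snapshot_experiment",
]


def _gaussian_potential() -> AnalyticPotential:
    return AnalyticPotential(
        lambda x: 0.5 * float(np.sum(np.asarray(x, dtype=float) ** 2)),
        lambda x: np.asarray(x, dtype=float),
        grad_batch=lambda p: np.asarray(p, dtype=float),
    )


def colony_radius_closed_form(sigma_s: float = 2.0, n_r: int = 1201) -> dict:
    """95%-mass radius of the initial ball density vs its closed form.

    The initial radial density p(r, 0) = 4 pi r^2 on [0, sigma_s] has
    cumulative mass proportional to r^3, so the mass-fraction radius is
    (0.95)^(1/3) sigma_s exactly.
    """
    r = np.linspace(0.0, 1.2 * sigma_s, n_r)
    p = np.where(r <= sigma_s, 4.0 * np.pi * r**2, 0.0)
    sol = ColonySolution(r, np.array([0.0]), p[:, None], (r <= sigma_s)[:, None].astype(float))
    measured = colony_radius(sol, 0, mass_fraction=0.95)
    return {
        "measured_ratio": measured / sigma_s,
        "closed_form_ratio": 0.95 ** (1.0 / 3.0),
    }


def _turing_conditions():
    theta = schnakenberg_default_theta()
    grid = TuringGrid((32, 32), 40.0)
    cfg = TuringSolverConfig(dt=0.15, t_max=150.0)

    def sim_items(th, n, seed):
        return pattern_items(simulate_turing_ensemble(th, grid, n, 0.01, seed, cfg))

    return theta, grid, sim_items


def turing_chi2_experiment(
    seed: int,
    n_replicates: int = 200,
    n_ens: int = 40,
    N: int = 10,
    M: int = 10,
) -> dict:
    """Distribution of the pattern-CIL cost at the true parameter vs chi^2(M)."""
    theta, grid, sim_items = _turing_conditions()
    rng = np.random.default_rng(seed)
    items = sim_items(theta, n_ens * N, int(rng.integers(2**31)))
    training = partition_items(
        items, n_ens, N, mode="pattern-subsets", cell_volume=grid.cell_volume
    )
    stats = estimate_statistics(training, M=M)
    costs = np.array(
        [
            cil_cost_at_parameter(theta, stats, sim_items, N, training, int(rng.integers(2**31)))
            for _ in range(n_replicates)
        ]
    )
    report = chi2_calibration(costs, stats.bins.M)
    report["M"] = stats.bins.M
    report["n_replicates"] = n_replicates
    return report


def lorenz_chi2_experiment(
    seed: int,
    n_replicates: int = 200,
    n_ens: int = 60,
    N: int = 50,
    M: int = 10,
    dt: float = 0.5,
) -> dict:
    """Distribution of the trajectory-CIL cost at the true parameter."""
    theta = lorenz63_default_theta()

    def sim_items(th, n, s):
        return trajectory_items(sample_attractor(th, n, dt, seed=s))

    rng = np.random.default_rng(seed)
    items = sim_items(theta, n_ens * N, int(rng.integers(2**31)))
    training = partition_items(items, n_ens, N, mode="trajectory-pair")
    stats = estimate_statistics(training, M=M)
    costs = np.array(
        [
            cil_cost_at_parameter(theta, stats, sim_items, N, training, int(rng.integers(2**31)))
            for _ in range(n_replicates)
        ]
    )
    report = chi2_calibration(costs, stats.bins.M)
    report["M"] = stats.bins.M
    report["n_replicates"] = n_replicates
    return report


def colony_recovery_experiment(
    seed: int,
    n_repetitions: int = 20,
    n_steps: int = 5000,
    burn: int = 2000,
) -> dict:
    """Coverage of the generating colony parameters by posterior intervals.

    Each repetition draws fresh noisy radius data at theta*, runs a short
    adaptive-Metropolis chain on the log-posterior and checks whether the
    central 95% marginal interval of every component contains the truth.
    Returns per-component coverage counts out of ``n_repetitions``.
    """
    names = ("alpha", "sigma_k", "sigma_s", "sigma_o")
    theta_star = np.array([0.3, 1.5, 2.0, 0.05])
    log_star = np.log(theta_star)
    times = np.linspace(0.0, 10.0, 10)
    truth_radii = colony_radii(
        ParameterVector(("alpha", "sigma_k", "sigma_s"), theta_star[:3]), times
    )
    prior = GaussianPrior(m=log_star, Sigma_prior=4.0 * np.eye(4))
    rng = np.random.default_rng(seed)
    covered = np.zeros(4, dtype=int)
    acceptance = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_repetitions):
            data_seed = int(rng.integers(2**31))
            meas = observe_radius(times, truth_radii, theta_star[3], data_seed)
            target = make_colony_potential(meas, prior, names)
            x0 = log_star + 0.05 * rng.standard_normal(4)
            chain = adaptive_metropolis(
                target, x0, n_steps, AdaptConfig(t0=200), seed=int(rng.integers(2**31))
            )
            post = chain.samples[burn:]
            lo, hi = np.percentile(post, [2.5, 97.5], axis=0)
            covered += ((lo <= log_star) & (log_star <= hi)).astype(int)
            acceptance.append(chain.acceptance_rate)
    return {
        "coverage_counts": covered.tolist(),
        "min_coverage_count": int(covered.min()),
        "n_repetitions": n_repetitions,
        "parameter_names": list(names),
        "mean_acceptance": float(np.mean(acceptance)),
    }


def ula_variance_experiment(
    seed: int,
    steps: tuple[float, ...] = (0.2, 0.1, 0.05),
    n_particles: int = 20_000,
) -> dict:
    """Stationary variance of unadjusted Langevin on V = theta^2/2.

    The Euler-Maruyama chain is exactly AR(1) with stationary variance
    1/(1 - h/2); several decorrelated snapshots are pooled to shrink the
    Monte Carlo error.
    """
    V = _gaussian_potential()
    out = {}
    rng = np.random.default_rng(seed)
    for h in steps:
        state = np.zeros((n_particles, 1))
        ens = langevin_sample(V, state, h, int(30 / h), seed=int(rng.integers(2**31)))
        pooled = [ens.positions]
        for _ in range(4):
            ens = langevin_sample(
                V, pooled[-1], h, int(3 / h), seed=int(rng.integers(2**31))
            )
            pooled.append(ens.positions)
        var = float(np.concatenate(pooled).var(ddof=1))
        expected = 1.0 / (1.0 - h / 2.0)
        out[h] = {
            "measured_variance": var,
            "closed_form": expected,
            # snapshots 3/h apart are effectively independent; be conservative
            "mc_standard_error": float(np.sqrt(2.0 / (2 * n_particles)) * expected),
        }
    return out


def fokker_planck_lyapunov_experiment() -> dict:
    """Mass conservation, discrete stationarity and KL decay of the 1-D flow."""
    V = _gaussian_potential()
    nodes = np.linspace(-12.0, 12.0, 481)
    rho0 = DensityGrid1D.from_unnormalised(nodes, np.exp(-(nodes**2) / 8.0))
    times, densities = fokker_planck_1d(V, rho0, dt=1e-3, T=2.0, store_every=100)
    masses = np.array([np.trapezoid(d.values, nodes) for d in densities])
    kls = kl_decay_monitor((times, densities), V)
    rho_inf = stationary_density(V, nodes)
    _, stat = fokker_planck_1d(V, rho_inf, dt=1e-3, T=1.0, store_every=1000)
    return {
        "max_mass_error": float(np.abs(masses - 1.0).max()),
        "stationarity_error": float(np.abs(stat[-1].values - rho_inf.values).max()),
        "max_kl_increase": float(np.max(np.diff(kls))),
        "kl_initial": float(kls[0]),
        "kl_final": float(kls[-1]),
    }


def svgd_experiment(seed: int = 0, n_particles: int = 100) -> dict:
    """Reduction, determinism and mean convergence of SVGD on a 1-D Gaussian."""
    V = _gaussian_potential()
    one = ParticleEnsemble(positions=np.array([[1.5]]))
    stepped = svgd_step(one, V, KernelSpec(bandwidth=2.0), dt=0.1)
    reduction_error = abs(stepped.positions[0, 0] - (1.5 - 0.1 * 1.5))

    init = np.random.default_rng(seed).normal(2.0, 0.5, size=(n_particles, 1))
    a = svgd_sample(V, init.copy(), dt=0.1, n_steps=1500)
    b = svgd_sample(V, init.copy(), dt=0.1, n_steps=1500)
    return {
        "one_particle_reduction_error": float(reduction_error),
        "deterministic": bool(np.array_equal(a.positions, b.positions)),
        "final_mean_abs": float(abs(a.positions.mean())),
    }


def oracle_equivalences(seed: int = 0) -> dict:
    """Implementation-vs-oracle residuals for three core computations.

    * Mahalanobis cost via Cholesky vs the dense matrix inverse,
    * eCDF vector vs brute-force enumeration of all point pairs,
    * recursive chain-history covariance vs batch recomputation.
    """
    from .cil import CILStatistics, ECDFVector, RadiusBins, cil_cost, pairwise_ecdf_trajectories

    rng = np.random.default_rng(seed)

    A = rng.normal(size=(5, 5))
    sigma = A @ A.T + 0.5 * np.eye(5)
    mu = np.sort(rng.random(5))
    bins = RadiusBins(np.arange(1.0, 6.0))
    stats = CILStatistics(mu=mu, sigma=sigma, bins=bins, n_realisations=99)
    y = ECDFVector(np.clip(np.sort(mu + 0.05 * rng.normal(size=5)), 0.0, 1.0), bins)
    r = y.y - mu
    mahal_err = abs(cil_cost(y, stats) - r @ np.linalg.inv(sigma) @ r)

    S, St = rng.normal(size=(7, 3)), rng.normal(size=(7, 3))
    bins2 = RadiusBins(np.array([0.5, 1.0, 2.0, 4.0]))
    y2 = pairwise_ecdf_trajectories(S, St, bins2).y
    brute = np.array(
        [
            sum(np.linalg.norm(s - t) < R for s in S for t in St) / 49.0
            for R in bins2.R
        ]
    )
    ecdf_err = float(np.abs(y2 - brute).max())

    xs = rng.normal(size=(400, 3))
    mom = _RunningMoments(3)
    for x in xs:
        mom.push(x)
    cov_err = float(np.abs(mom.cov - np.cov(xs, rowvar=False)).max())

    return {
        "mahalanobis_vs_dense_inverse": float(mahal_err),
        "ecdf_vs_brute_force": ecdf_err,
        "recursive_vs_batch_covariance": cov_err,
    }


def scil_single_snapshot_experiment(
    seed: int,
    n_replicates: int = 150,
    n_ens_sim: int = 20,
    N: int = 10,
    M: int = 10,
) -> dict:
    """SCIL cost with a single observed pattern: finiteness and chi^2 fit.

    Synthetic statistics are estimated once at the true parameter (the
    realisation structure matches the data vector: one pattern against a
    reference subset of N), then replicate costs are computed for fresh
    single-pattern data sets.
    """
    theta, grid, sim_items = _turing_conditions()
    rng = np.random.default_rng(seed)
    stats, _ = scil_statistics(
        theta, sim_items, n_data=1, N=N, n_ens_sim=n_ens_sim,
        seed=int(rng.integers(2**31)), M=M, cell_volume=grid.cell_volume,
    )
    costs = []
    for _ in range(n_replicates):
        data = sim_items(theta, 1, int(rng.integers(2**31)))
        costs.append(
            scil_cost(
                theta, data, sim_items, N=N, n_ens_sim=n_ens_sim,
                seed=int(rng.integers(2**31)), cell_volume=grid.cell_volume, stats=stats,
            )
        )
    costs = np.array(costs)
    report = chi2_calibration(costs, stats.bins.M)
    report["M"] = stats.bins.M
    report["all_finite"] = bool(np.all(np.isfinite(costs)))
    report["n_replicates"] = n_replicates
    return report
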