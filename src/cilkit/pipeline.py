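"""End-to-end pipeline: simulate -> build likelihood -> sample -> diagnose.

``run_pipeline`` executes a validated :class:`~cilkit.config.RunConfig`,
writes the chain, a diagnostics report and a provenance log (config hash,
seeds, version) to the configured output directory, and returns the result
bundle in memory.  Any stage failure aborts with a stage-named
:class:`PipelineError`; partial outputs are retained next to a ``.partial``
marker file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .bayes import GaussianPrior, make_colony_potential
from .cil import (
    cil_cost_at_parameter,
    estimate_statistics,
    partition_items,
    pattern_items,
    scil_cost,
    trajectory_items,
)
from .config import RunConfig
from .errors import CilkitError, PipelineError
from .forward_models import (
    ParameterVector,
    RadiusMeasurements,
    TuringGrid,
    TuringSolverConfig,
    colony_radii,
    observe_radius,
    sample_attractor,
    simulate_turing_ensemble,
)
from .mcmc import AdaptConfig, adaptive_metropolis, chain_diagnostics, metropolis

logger = logging.getLogger("cilkit.pipeline")

__all__ = ["run_pipeline", "make_cil_log_target"]


def _theta_from_model(model: dict, names: tuple[str, ...]) -> ParameterVector:
    return ParameterVector(names, np.array([float(model[n]) for n in names]))


def _turing_simulator(model: dict):
    grid = TuringGrid((int(model["grid_n"]),), float(model["grid_length"]))
    cfg = TuringSolverConfig(dt=float(model["dt"]), t_max=float(model["t_int"]))

    def simulate_items(theta: ParameterVector, n: int, seed: int) -> np.ndarray:
        ens = simulate_turing_ensemble(theta, grid, n, float(model["ic_amplitude"]), seed, cfg)
        return pattern_items(ens)

    return simulate_items, grid.cell_volume


def _lorenz_simulator(model: dict):
    def simulate_items(theta: ParameterVector, n: int, seed: int) -> np.ndarray:
        traj = sample_attractor(
            theta,
            n_points=n,
            dt=float(model["dt"]),
            transient=float(model["transient"]),
            epsilon=float(model["epsilon"]),
            seed=seed,
        )
        return trajectory_items(traj)

    return simulate_items, 1.0


def make_cil_log_target(
    cfg: RunConfig,
    rng: np.random.Generator,
):
    """Build the CIL/SCIL log-target -f(theta)/2 for the configured model.

    Training data are simulated at the config's parameter values; candidate
    parameters named in ``[likelihood] infer`` are sampled on the log scale
    while the remaining components stay fixed.
    """
    model = cfg.model
    like = cfg.likelihood
    name = model["name"]
    if name == "turing":
        theta_names = ("a", "b", "gamma", "d_u", "d_v")
        simulate_items, cell_volume = _turing_simulator(model)
    elif name == "lorenz63":
        theta_names = ("sigma", "rho", "beta")
        simulate_items, cell_volume = _lorenz_simulator(model)
    else:
        raise PipelineError(f"model {name!r} has no CIL target")
    theta0 = _theta_from_model(model, theta_names)
    infer = tuple(s.strip() for s in str(like["infer"]).split(",") if s.strip())
    if not infer:
        infer = theta_names[:1]
    idx = [theta_names.index(n) for n in infer]

    metric = str(like["metric"])
    n_ens, N, M = int(like["n_ens"]), int(like["n_per_subset"]), int(like["m_bins"])
    mode = str(like["mode"])

    def theta_from_x(x: np.ndarray) -> ParameterVector:
        values = theta0.values.copy()
        values[idx] = np.exp(np.asarray(x, dtype=float))
        return theta0.replace_values(values)

    x0 = np.log(theta0.values[idx])

    if mode == "cil":
        train_items = simulate_items(theta0, n_ens * N, int(rng.integers(2**31)))
        training = partition_items(
            train_items, n_ens, N, mode="pattern-subsets" if name == "turing" else "trajectory-pair",
            metric_id=metric, cell_volume=cell_volume,
        )
        stats = estimate_statistics(training, M=M)

        def log_target(x: np.ndarray) -> float:
            theta = theta_from_x(x)
            seed = int(rng.integers(2**31))
            try:
                f = cil_cost_at_parameter(theta, stats, simulate_items, N, training, seed)
            except CilkitError:
                return -np.inf
            return -0.5 * f

        return log_target, x0, infer

    # scil: data is n_data observed items at theta0
    n_data = int(like["n_data"])
    data_items = simulate_items(theta0, n_data, int(rng.integers(2**31)))

    def log_target(x: np.ndarray) -> float:
        theta = theta_from_x(x)
        seed = int(rng.integers(2**31))
        try:
            f = scil_cost(
                theta, data_items, simulate_items, N=N, n_ens_sim=n_ens, seed=seed,
                M=M, metric_id=metric, cell_volume=cell_volume,
            )
        except CilkitError:
            return -np.inf
        return -0.5 * f

    return log_target, x0, infer


def _bayes_target(cfg: RunConfig, rng: np.random.Generator):
    model = cfg.model
    like = cfg.likelihood
    names = ("alpha", "sigma_k", "sigma_s", "sigma_o")
    theta_star = {n: float(model[n]) for n in names}
    data_path = str(like["data"])
    if data_path:
        meas = RadiusMeasurements.from_csv(data_path)
    else:
        times = np.linspace(0.0, float(model["t_max"]), int(model["n_times"]))
        theta_sim = ParameterVector(
            ("alpha", "sigma_k", "sigma_s"),
            np.array([theta_star["alpha"], theta_star["sigma_k"], theta_star["sigma_s"]]),
        )
        radii = colony_radii(
            theta_sim, times, r_max=float(model["r_max"]), n_r=int(model["n_r"])
        )
        meas = observe_radius(times, radii, theta_star["sigma_o"], int(like["data_seed"]))
    log_theta0 = np.log(np.array([theta_star[n] for n in names]))
    prior = GaussianPrior(m=log_theta0, Sigma_prior=4.0 * np.eye(4))
    target = make_colony_potential(
        meas, prior, names, r_max=float(model["r_max"]), n_r=int(model["n_r"])
    )
    return target, log_theta0, names


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the configured inference run; see module docstring."""
    out = Path(out_dir) if out_dir is not None else Path(str(cfg.output["dir"]))
    out.mkdir(parents=True, exist_ok=True)
    marker = out / ".partial"
    marker.write_text("run in progress\n")
    seed = int(cfg.sampler["seed"])
    rng = np.random.default_rng(seed)
    t_start = time.time()
    stage = "setup"
    try:
        stage = "build-likelihood"
        mode = str(cfg.likelihood["mode"])
        if mode == "bayes":
            log_target, x0, names = _bayes_target(cfg, rng)
        else:
            log_target, x0, names = make_cil_log_target(cfg, rng)
        logger.info("[%s] target over %s ready", stage, names)

        stage = "sample"
        steps = int(cfg.sampler["steps"])
        algo = str(cfg.sampler["algorithm"])
        if algo == "metropolis":
            chain = metropolis(log_target, x0, float(cfg.sampler["step_s"]), steps, seed)
        else:
            chain = adaptive_metropolis(
                log_target, x0, steps, AdaptConfig(t0=int(cfg.sampler["t0"])), seed
            )
        logger.info("[%s] %d steps, acceptance %.3f", stage, steps, chain.acceptance_rate)

        stage = "diagnose"
        report = chain_diagnostics(chain, float(cfg.sampler["burn_in"]))

        stage = "write-output"
        chain.to_csv(out / "chain.csv", names=list(names))
        diag = {
            "acceptance_rate": report["acceptance_rate"],
            "ess": report["ess"].tolist(),
            "posterior_mean": report["posterior_mean"].tolist(),
            "posterior_cov": report["posterior_cov"].tolist(),
            "parameter_names": list(names),
        }
        (out / "diagnostics.json").write_text(json.dumps(diag, indent=2) + "\n")
        cfg_blob = json.dumps(cfg.as_dict(), sort_keys=True)
        provenance = {
            "config_sha256": hashlib.sha256(cfg_blob.encode()).hexdigest(),
            "seed": seed,
            "version": __version__,
            "elapsed_s": time.time() - t_start,
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")
        marker.unlink()
        return {"chain": chain, "diagnostics": report, "provenance": provenance, "out_dir": out}
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
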