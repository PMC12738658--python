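"""Correlation-integral likelihood (CIL) and its synthetic variant (SCIL).

The central object is the generalised correlation-integral vector: the
empirical CDF, at fixed radii R_1 < ... < R_M, of the distances between two
collections of items.  For chaotic systems the items are state-space points
of two trajectories and the eCDF is taken over all N^2 point pairs; for
pattern-formation models the items are whole spatial patterns and the eCDF
is taken over pattern-to-pattern distances.  Both cases reduce to the same
computation on "item matrices" (one row per state point or per flattened
pattern), which is how this module represents them internally.

At a fixed parameter the eCDF vector is approximately Gaussian
(CLT over many weakly dependent distances), so a training set partitioned
into ``n_ens`` subsets yields ``n_ens (n_ens - 1) / 2`` realisations from
which a mean mu and covariance Sigma are estimated.  The stochastic cost

    f(theta) = (y(theta) - mu)^T Sigma^{-1} (y(theta) - mu)

is a Mahalanobis distance and satisfies f(theta_0) ~ chi^2(M) at the true
parameter.  The synthetic variant (SCIL) interchanges the roles of data and
simulation: mu and Sigma are estimated from repeated simulations at the
candidate theta, so inference remains possible down to a single observed
pattern.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist
from scipy.stats import chi2 as chi2_dist
from scipy.stats import kstest

from .errors import BinsDegenerateError, ValidationError
from .forward_models.types import PatternEnsemble, TrajectorySet

__all__ = [
    "RadiusBins",
    "ECDFVector",
    "DistanceSample",
    "CILStatistics",
    "TrainingSubsets",
    "pattern_distance",
    "cross_distances",
    "pairwise_ecdf_trajectories",
    "ecdf_patterns",
    "select_radii",
    "trajectory_items",
    "pattern_items",
    "partition_items",
    "estimate_statistics",
    "cil_cost",
    "cil_cost_at_parameter",
    "scil_statistics",
    "scil_cost",
    "chi2_calibration",
    "register_metric",
]

# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class RadiusBins:
    """Strictly increasing positive bin radii R_1 < ... < R_M."""

    R: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.R, dtype=float)
        object.__setattr__(self, "R", R)
        if R.ndim != 1 or R.size < 2:
            raise ValidationError("bins need at least two radii")
        if R[0] <= 0 or not np.all(np.diff(R) > 0):
            raise ValidationError("bin radii must be positive and strictly increasing")

    @property
    def M(self) -> int:
        return self.R.size

    def __eq__(self, other) -> bool:
        return isinstance(other, RadiusBins) and np.array_equal(self.R, other.R)


@dataclass(frozen=True)
class ECDFVector:
    """Correlation-integral vector y with its bins; componentwise in [0, 1]."""

    y: np.ndarray
    bins: RadiusBins
    source: str = "unspecified"

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "y", y)
        if y.shape != (self.bins.M,):
            raise ValidationError("y must have one component per bin")
        if np.any(y < 0) or np.any(y > 1):
            raise ValidationError("eCDF components must lie in [0, 1]")
        if np.any(np.diff(y) < 0):
            raise ValidationError("eCDF must be non-decreasing across bins")

    def to_csv(self, path) -> None:
        """Write (radius, y) pairs as delimited text for external plotting."""
        np.savetxt(
            path,
            np.column_stack([self.bins.R, self.y]),
            delimiter=",",
            header="radius,y",
            comments="",
            fmt="%.17g",
        )


@dataclass(frozen=True)
class DistanceSample:
    """Non-negative finite distances with the identifier of their metric."""

    values: np.ndarray
    metric_id: str = "L2"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", values)
        if values.size == 0:
            raise ValidationError("distance sample must be non-empty")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValidationError("distances must be finite and non-negative")

    def to_csv(self, path) -> None:
        """Write the distances as one delimited-text column."""
        np.savetxt(path, self.values, delimiter=",", header=self.metric_id, comments="", fmt="%.17g")


@dataclass
class CILStatistics:
    """Estimated Gaussian statistics (mu, Sigma) of the eCDF vector.

    ``sigma`` stores the regularised covariance actually used in the
    Mahalanobis cost; ``regularisation`` is the ridge lambda applied as
    Sigma + lambda * tr(Sigma)/M * I (escalated until the Cholesky
    factorisation succeeds).
    """

    mu: np.ndarray
    sigma: np.ndarray
    bins: RadiusBins
    n_realisations: int
    metric_id: str = "L2"
    mode: str = "pattern-subsets"
    regularisation: float = 1e-8
    _factor: tuple | None = field(default=None, repr=False, compare=False)

    def factor(self):
        if self._factor is None:
            self._factor = cho_factor(self.sigma, lower=True)
        return self._factor

    # -- serialisation: one container file, JSON header line + raw blocks --

    def save(self, path: str | Path) -> None:
        header = json.dumps(
            {
                "M": self.bins.M,
                "bins": self.bins.R.tolist(),
                "n_realisations": self.n_realisations,
                "metric_id": self.metric_id,
                "mode": self.mode,
                "regularisation": self.regularisation,
            }
        ).encode()
        with open(path, "wb") as fh:
            fh.write(struct.pack("<I", len(header)))
            fh.write(header)
            fh.write(self.mu.astype("<f8").tobytes())
            fh.write(self.sigma.astype("<f8").tobytes())

    @classmethod
    def load(cls, path: str | Path) -> "CILStatistics":
        with open(path, "rb") as fh:
            (hlen,) = struct.unpack("<I", fh.read(4))
            meta = json.loads(fh.read(hlen).decode())
            M = meta["M"]
            mu = np.frombuffer(fh.read(8 * M), dtype="<f8").copy()
            sigma = np.frombuffer(fh.read(8 * M * M), dtype="<f8").reshape(M, M).copy()
        return cls(
            mu=mu,
            sigma=sigma,
            bins=RadiusBins(np.array(meta["bins"])),
            n_realisations=meta["n_realisations"],
            metric_id=meta["metric_id"],
            mode=meta["mode"],
            regularisation=meta["regularisation"],
        )


@dataclass(frozen=True)
class TrainingSubsets:
    """Partitioned training data as item matrices (one row per item).

    ``mode`` records whether items are trajectory points or flattened
    patterns; ``cell_volume`` is the grid weight folded into pattern norms.
    """

    items: tuple[np.ndarray, ...]
    mode: str
    metric_id: str = "L2"
    cell_volume: float = 1.0

    def __post_init__(self):
        items = tuple(np.atleast_2d(np.asarray(s, dtype=float)) for s in self.items)
        object.__setattr__(self, "items", items)
        dims = {s.shape[1] for s in items}
        if len(dims) != 1:
            raise ValidationError("all subsets must share the item dimension")

    @property
    def n_subsets(self) -> int:
        return len(self.items)


# ---------------------------------------------------------------------------
# metrics


def _euclidean(a, b, cv):
    return cdist(a, b) * np.sqrt(cv)


def _manhattan(a, b, cv):
    return cdist(a, b, metric="cityblock") * cv


def _chebyshev(a, b, cv):
    return cdist(a, b, metric="chebyshev")


_METRICS: dict[str, Callable] = {"L2": _euclidean, "L1": _manhattan, "Linf": _chebyshev}


def register_metric(name: str, fn: Callable) -> None:
    """Register a cross-distance function ``fn(A, B, cell_volume) -> matrix``."""
    _METRICS[name] = fn


def _metric(name: str) -> Callable:
    try:
        return _METRICS[name]
    except KeyError:
        raise ValidationError(f"unknown metric {name!r}; known: {sorted(_METRICS)}")


def cross_distances(
    items_a: np.ndarray, items_b: np.ndarray, metric_id: str = "L2", cell_volume: float = 1.0
) -> np.ndarray:
    """All pairwise distances between two item matrices (n_a x n_b)."""
    a = np.atleast_2d(np.asarray(items_a, dtype=float))
    b = np.atleast_2d(np.asarray(items_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValidationError("item dimensions differ")
    return _metric(metric_id)(a, b, cell_volume)


def pattern_distance(p1: np.ndarray, p2: np.ndarray, metric_id: str = "L2", cell_volume: float = 1.0) -> float:
    """Grid-weighted norm of the difference of two patterns."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValidationError(f"pattern shapes differ: {p1.shape} vs {p2.shape}")
    return float(cross_distances(p1.ravel()[None], p2.ravel()[None], metric_id, cell_volume)[0, 0])


# ---------------------------------------------------------------------------
# eCDF vectors


def _ecdf(distances: np.ndarray, bins: RadiusBins) -> np.ndarray:
    d = np.sort(np.asarray(distances, dtype=float).ravel())
    # strict inequality: count of distances < R_k
    return np.searchsorted(d, bins.R, side="left") / d.size


def pairwise_ecdf_trajectories(
    S: TrajectorySet | np.ndarray,
    S_tilde: TrajectorySet | np.ndarray,
    bins: RadiusBins,
    norm_id: str = "L2",
    component_mask: Sequence[bool] | None = None,
) -> ECDFVector:
    """y_k = (1/N^2) #{(i, j): ||s_i - s~_j|| < R_k} over all point pairs."""
    a = S.observed(component_mask) if isinstance(S, TrajectorySet) else np.atleast_2d(S)
    b = (
        S_tilde.observed(component_mask)
        if isinstance(S_tilde, TrajectorySet)
        else np.atleast_2d(S_tilde)
    )
    d = cross_distances(a, b, norm_id)
    return ECDFVector(y=_ecdf(d, bins), bins=bins, source="trajectory-pair")


def ecdf_patterns(d: DistanceSample, bins: RadiusBins) -> ECDFVector:
    """y_k = (1/n) #{i: d_i < R_k} over a sample of pattern distances."""
    return ECDFVector(y=_ecdf(d.values, bins), bins=bins, source="pattern-subsets")


def select_radii(training_distances: DistanceSample, M: int = 10, scheme: str = "quantile") -> RadiusBins:
    """Place bin radii at equally spaced quantiles of the training distances.

    Duplicate quantiles (possible for discrete distance distributions) are
    collapsed and the reduced bin count reported via a warning; fewer than
    two distinct radii raise :class:`BinsDegenerateError`.
    """
    if M < 2:
        raise ValidationError("need at least two bins")
    if scheme != "quantile":
        raise ValidationError(f"unknown bin-selection scheme {scheme!r}")
    d = training_distances.values
    qs = np.arange(1, M + 1) / (M + 1)
    radii = np.unique(np.quantile(d, qs))
    radii = radii[radii > 0]
    if radii.size < 2:
        raise BinsDegenerateError(
            f"only {radii.size} distinct positive quantile(s); distances too concentrated"
        )
    if radii.size < M:
        warnings.warn(
            f"duplicate quantiles collapsed: {M} bins requested, {radii.size} kept",
            stacklevel=2,
        )
    return RadiusBins(radii)


# ---------------------------------------------------------------------------
# item adapters and partitioning


def trajectory_items(traj: TrajectorySet, component_mask: Sequence[bool] | None = None) -> np.ndarray:
    """Trajectory as an item matrix (one row per sampled state)."""
    return traj.observed(component_mask)


def pattern_items(ens: PatternEnsemble) -> np.ndarray:
    """Pattern ensemble as an item matrix (one row per flattened pattern)."""
    obs = ens.observed()
    return obs.reshape(obs.shape[0], -1)


def partition_items(
    items: np.ndarray,
    n_ens: int,
    N: int,
    mode: str,
    metric_id: str = "L2",
    cell_volume: float = 1.0,
    seed: int | None = None,
) -> TrainingSubsets:
    """Split an item matrix into ``n_ens`` contiguous blocks of ``N`` items.

    With a seed, items are shuffled once before blocking (useful when the
    stored order is not exchangeable).  Requires at least ``n_ens * N``
    items; surplus items are dropped from the tail.
    """
    items = np.atleast_2d(np.asarray(items, dtype=float))
    if n_ens < 3:
        raise ValidationError("n_ens must be at least 3 to estimate a covariance")
    if items.shape[0] < n_ens * N:
        raise ValidationError(
            f"{items.shape[0]} items cannot form {n_ens} subsets of {N}"
        )
    if seed is not None:
        perm = np.random.default_rng(seed).permutation(items.shape[0])
        items = items[perm]
    blocks = tuple(items[k * N : (k + 1) * N] for k in range(n_ens))
    return TrainingSubsets(items=blocks, mode=mode, metric_id=metric_id, cell_volume=cell_volume)


# ---------------------------------------------------------------------------
# statistics estimation and costs


def _regularise(sigma: np.ndarray, lam: float) -> tuple[np.ndarray, tuple, float]:
    M = sigma.shape[0]
    scale = np.trace(sigma) / M
    if scale <= 0:
        scale = 1.0
    current = lam
    for _ in range(40):
        candidate = sigma + current * scale * np.eye(M)
        try:
            factor = cho_factor(candidate, lower=True)
            return candidate, factor, current
        except np.linalg.LinAlgError:
            current *= 10.0
    raise ValidationError("covariance could not be regularised to positive definiteness")


def estimate_statistics(
    training: TrainingSubsets,
    bins: RadiusBins | None = None,
    M: int = 10,
    regularisation: float = 1e-8,
) -> CILStatistics:
    """Estimate (mu, Sigma) of the eCDF vector from all subset pairs.

    Every unordered pair of the ``n_ens`` training subsets yields one
    realisation of the correlation-integral vector (cross distances between
    the two subsets, then the eCDF at the bin radii), for
    ``n_ens (n_ens - 1) / 2`` realisations in total.  When ``bins`` is not
    given, radii are placed at quantiles of the pooled pair distances.
    """
    n_ens = training.n_subsets
    if n_ens < 3:
        raise ValidationError("need at least 3 subsets")
    pair_distances = []
    for k in range(n_ens):
        for l in range(k + 1, n_ens):
            d = cross_distances(
                training.items[k], training.items[l], training.metric_id, training.cell_volume
            )
            pair_distances.append(d.ravel())
    if bins is None:
        pooled = DistanceSample(np.concatenate(pair_distances), training.metric_id)
        bins = select_radii(pooled, M)
    realisations = np.array([_ecdf(d, bins) for d in pair_distances])
    n_real = realisations.shape[0]
    if n_real <= bins.M:
        warnings.warn(
            f"{n_real} realisations for {bins.M} bins: covariance is rank deficient, "
            "regularisation is mandatory",
            stacklevel=2,
        )
    mu = realisations.mean(axis=0)
    sigma = np.cov(realisations, rowvar=False, ddof=1)
    sigma_reg, factor, lam = _regularise(np.atleast_2d(sigma), regularisation)
    stats = CILStatistics(
        mu=mu,
        sigma=sigma_reg,
        bins=bins,
        n_realisations=n_real,
        metric_id=training.metric_id,
        mode=training.mode,
        regularisation=lam,
    )
    stats._factor = factor
    return stats


def cil_cost(y: ECDFVector, stats: CILStatistics) -> float:
    """Mahalanobis cost f = (y - mu)^T Sigma^{-1} (y - mu) >= 0."""
    if y.bins != stats.bins:
        raise ValidationError("eCDF vector and statistics use different bins")
    r = y.y - stats.mu
    return float(r @ cho_solve(stats.factor(), r))


def cil_cost_at_parameter(
    theta,
    stats: CILStatistics,
    simulate_items: Callable[[object, int, int], np.ndarray],
    N: int,
    training: TrainingSubsets,
    seed: int = 0,
) -> float:
    """Stochastic CIL cost at a candidate parameter (large-data variant).

    ``simulate_items(theta, n, seed)`` must return an item matrix of ``n``
    fresh model items (trajectory points or flattened patterns) at ``theta``.
    The eCDF vector is formed between the simulated items and one randomly
    chosen (seeded) training subset, then evaluated against ``stats``.
    """
    rng = np.random.default_rng(seed)
    subset = training.items[int(rng.integers(training.n_subsets))]
    sim_seed = int(rng.integers(2**31))
    items = simulate_items(theta, N, sim_seed)
    d = cross_distances(items, subset, training.metric_id, training.cell_volume)
    y = ECDFVector(_ecdf(d, stats.bins), stats.bins, source="data-vs-sim")
    return cil_cost(y, stats)


def scil_statistics(
    theta,
    simulate_items: Callable[[object, int, int], np.ndarray],
    n_data: int,
    N: int,
    n_ens_sim: int,
    seed: int,
    bins: RadiusBins | None = None,
    M: int = 10,
    metric_id: str = "L2",
    cell_volume: float = 1.0,
    regularisation: float = 1e-8,
) -> tuple[CILStatistics, TrainingSubsets]:
    """Synthetic eCDF statistics at a candidate parameter (limited data).

    Simulates ``n_ens_sim`` reference subsets of ``N`` items plus
    ``n_ens_sim`` pseudo-data groups of ``n_data`` items, all at ``theta``,
    and forms one realisation per (pseudo-data group, reference subset)
    pair.  The realisation structure therefore matches the data vector
    (``n_data`` observed items against ``N`` simulated ones), which keeps
    the chi^2(M) calibration valid down to a single observed pattern.
    """
    rng = np.random.default_rng(seed)
    n_items = n_ens_sim * (N + n_data)
    pool = simulate_items(theta, n_items, int(rng.integers(2**31)))
    pool = np.atleast_2d(np.asarray(pool, dtype=float))
    refs = [pool[k * N : (k + 1) * N] for k in range(n_ens_sim)]
    off = n_ens_sim * N
    pseudo = [pool[off + k * n_data : off + (k + 1) * n_data] for k in range(n_ens_sim)]

    pair_distances = [
        cross_distances(p, r, metric_id, cell_volume).ravel() for p in pseudo for r in refs
    ]
    if bins is None:
        pooled = DistanceSample(np.concatenate(pair_distances), metric_id)
        bins = select_radii(pooled, M)
    realisations = np.array([_ecdf(d, bins) for d in pair_distances])
    mu = realisations.mean(axis=0)
    sigma = np.cov(realisations, rowvar=False, ddof=1)
    sigma_reg, factor, lam = _regularise(np.atleast_2d(sigma), regularisation)
    stats = CILStatistics(
        mu=mu,
        sigma=sigma_reg,
        bins=bins,
        n_realisations=realisations.shape[0],
        metric_id=metric_id,
        mode="scil",
        regularisation=lam,
    )
    stats._factor = factor
    subsets = TrainingSubsets(tuple(refs), mode="scil", metric_id=metric_id, cell_volume=cell_volume)
    return stats, subsets


def scil_cost(
    theta,
    data_items: np.ndarray,
    simulate_items: Callable[[object, int, int], np.ndarray],
    N: int,
    n_ens_sim: int,
    seed: int,
    bins: RadiusBins | None = None,
    M: int = 10,
    metric_id: str = "L2",
    cell_volume: float = 1.0,
    stats: CILStatistics | None = None,
) -> float:
    """Synthetic CIL cost: data (possibly a single pattern) vs simulations.

    The Gaussian statistics are estimated from simulations at ``theta``
    (see :func:`scil_statistics`), a fresh reference subset of ``N`` items
    is simulated, and the data eCDF against that subset is scored with the
    Mahalanobis cost.  Pass a precomputed ``stats`` to reuse the synthetic
    statistics across evaluations at the same theta.
    """
    data = np.atleast_2d(np.asarray(data_items, dtype=float))
    rng = np.random.default_rng(seed)
    if stats is None:
        stats, _ = scil_statistics(
            theta,
            simulate_items,
            n_data=data.shape[0],
            N=N,
            n_ens_sim=n_ens_sim,
            seed=int(rng.integers(2**31)),
            bins=bins,
            M=M,
            metric_id=metric_id,
            cell_volume=cell_volume,
        )
    fresh = simulate_items(theta, N, int(rng.integers(2**31)))
    d = cross_distances(data, fresh, metric_id, cell_volume)
    y = ECDFVector(_ecdf(d, stats.bins), stats.bins, source="data-vs-sim")
    return cil_cost(y, stats)


def chi2_calibration(costs: np.ndarray, M: int) -> dict[str, float]:
    """Compare replicate costs at the true parameter against chi^2(M).

    Returns the mean cost over M (1 for a perfectly calibrated cost) and a
    Kolmogorov-Smirnov test of the empirical cost distribution against the
    chi^2(M) reference.
    """
    costs = np.asarray(costs, dtype=float)
    if costs.size < 50:
        raise ValidationError("need at least 50 replicate costs for calibration")
    if np.any(costs < 0):
        raise ValidationError("costs must be non-negative")
    ks = kstest(costs, chi2_dist(M).cdf)
    return {
        "mean_ratio": float(costs.mean() / M),
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
    }
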