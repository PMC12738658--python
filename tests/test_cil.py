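"""Correlation-integral vectors, Gaussian statistics and Mahalanobis costs."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from cilkit.cil import (
    CILStatistics,
    DistanceSample,
    ECDFVector,
    RadiusBins,
    chi2_calibration,
    cil_cost,
    cil_cost_at_parameter,
    cross_distances,
    ecdf_patterns,
    estimate_statistics,
    pairwise_ecdf_trajectories,
    partition_items,
    pattern_distance,
    pattern_items,
    scil_cost,
    select_radii,
    trajectory_items,
)
from cilkit.errors import BinsDegenerateError, ValidationError
from cilkit.forward_models import (
    TuringSolverConfig,
    simulate_turing_ensemble,
)


class TestPairwiseEcdf:
    def test_brute_force_enumeration_example(self):
        # S = {0, 1}, S~ = {0, 2}: distances {0, 2, 1, 1}
        S = np.array([[0.0], [1.0]])
        St = np.array([[0.0], [2.0]])
        bins = RadiusBins(np.array([0.5, 1.5, 2.5]))
        y = pairwise_ecdf_trajectories(S, St, bins)
        assert np.allclose(y.y, [0.25, 0.75, 1.0])

    def test_bins_beyond_diameter_saturate_at_one(self):
        rng = np.random.default_rng(0)
        S, St = rng.random((5, 3)), rng.random((5, 3))
        bins = RadiusBins(np.array([10.0, 20.0]))
        assert np.allclose(pairwise_ecdf_trajectories(S, St, bins).y, 1.0)

    def test_symmetric_under_swapping_the_trajectories(self):
        rng = np.random.default_rng(1)
        S, St = rng.random((8, 2)), rng.random((8, 2))
        bins = RadiusBins(np.array([0.2, 0.5, 1.0]))
        a = pairwise_ecdf_trajectories(S, St, bins)
        b = pairwise_ecdf_trajectories(St, S, bins)
        assert np.array_equal(a.y, b.y)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_ecdf_trajectories(
                np.zeros((3, 2)), np.zeros((3, 3)), RadiusBins(np.array([1.0, 2.0]))
            )

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_ecdf_always_monotone_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        S, St = rng.normal(size=(6, 2)), rng.normal(size=(6, 2))
        bins = RadiusBins(np.sort(rng.random(5)) + np.linspace(0.01, 0.05, 5))
        y = pairwise_ecdf_trajectories(S, St, bins).y
        assert np.all((0 <= y) & (y <= 1))
        assert np.all(np.diff(y) >= 0)


class TestPatternDistance:
    def test_identity_is_zero(self):
        p = np.random.default_rng(0).random((4, 4))
        assert pattern_distance(p, p) == 0.0

    def test_hand_computed_l2(self):
        assert pattern_distance(np.array([0.0, 0.0]), np.array([1.0, 1.0])) == pytest.approx(
            np.sqrt(2.0)
        )

    def test_grid_weighting_scales_norms(self):
        p1, p2 = np.zeros(3), np.ones(3)
        assert pattern_distance(p1, p2, "L2", cell_volume=0.25) == pytest.approx(np.sqrt(3 * 0.25))
        assert pattern_distance(p1, p2, "L1", cell_volume=0.25) == pytest.approx(0.75)
        assert pattern_distance(p1, p2, "Linf", cell_volume=0.25) == pytest.approx(1.0)

    def test_symmetry_on_random_inputs(self):
        rng = np.random.default_rng(3)
        for metric in ("L2", "L1", "Linf"):
            a, b = rng.random(6), rng.random(6)
            assert pattern_distance(a, b, metric) == pytest.approx(pattern_distance(b, a, metric))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            pattern_distance(np.zeros(3), np.zeros(4))


class TestEcdfPatterns:
    def test_direct_count_example(self):
        d = DistanceSample(np.array([1.0, 2.0, 3.0]))
        bins = RadiusBins(np.array([1.5, 2.5, 3.5]))
        assert np.allclose(ecdf_patterns(d, bins).y, [1 / 3, 2 / 3, 1.0])

    def test_all_distances_beyond_bins_give_zero_vector(self):
        d = DistanceSample(np.array([5.0, 6.0]))
        bins = RadiusBins(np.array([1.0, 2.0]))
        assert np.allclose(ecdf_patterns(d, bins).y, 0.0)

    def test_ties_below_threshold_counted(self):
        d = DistanceSample(np.array([1.0, 1.0, 1.0]))
        bins = RadiusBins(np.array([2.0, 3.0]))
        assert np.allclose(ecdf_patterns(d, bins).y, 1.0)

    def test_tie_at_bin_edge_counts_as_outside(self):
        # strict "<": a distance exactly at the bin radius is not counted
        d = DistanceSample(np.array([1.0, 2.0]))
        bins = RadiusBins(np.array([1.0, 2.0, 2.5]))
        assert np.allclose(ecdf_patterns(d, bins).y, [0.0, 0.5, 1.0])


class TestSelectRadii:
    def test_quantiles_of_uniform_distances(self):
        rng = np.random.default_rng(5)
        d = DistanceSample(rng.random(10_000))
        bins = select_radii(d, M=4)
        assert np.allclose(bins.R, [0.2, 0.4, 0.6, 0.8], atol=0.05)

    def test_constant_distances_degenerate(self):
        with pytest.raises(BinsDegenerateError):
            select_radii(DistanceSample(np.full(100, 2.0)), M=4)

    def test_duplicate_quantiles_collapse_with_warning(self):
        d = DistanceSample(
            np.concatenate([np.full(50, 1.0), np.full(25, 2.0), np.linspace(3.0, 4.0, 25)])
        )
        with pytest.warns(UserWarning, match="collapsed"):
            bins = select_radii(d, M=8)
        assert np.all(np.diff(bins.R) > 0)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_bins_strictly_increasing(self, seed):
        rng = np.random.default_rng(seed)
        bins = select_radii(DistanceSample(rng.random(500) + 0.01), M=6)
        assert np.all(np.diff(bins.R) > 0)


class TestEstimateStatistics:
    def _subsets(self, n_ens, N=4, dim=3, seed=0):
        rng = np.random.default_rng(seed)
        return partition_items(rng.normal(size=(n_ens * N, dim)), n_ens, N, mode="trajectory-pair")

    def test_ten_subsets_give_45_realisations(self):
        stats = estimate_statistics(self._subsets(10), M=5)
        assert stats.n_realisations == 45

    def test_identical_subsets_have_zero_covariance_before_regularisation(self):
        block = np.random.default_rng(1).random((4, 2))
        training = partition_items(np.tile(block, (5, 1)), 5, 4, mode="pattern-subsets")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stats = estimate_statistics(training, M=3)
        off_ridge = stats.sigma - np.diag(np.diag(stats.sigma))
        assert np.allclose(off_ridge, 0.0)
        assert np.all(np.diag(stats.sigma) > 0)  # ridge made it positive definite

    def test_mean_is_valid_ecdf(self):
        stats = estimate_statistics(self._subsets(8), M=6)
        assert np.all((0 <= stats.mu) & (stats.mu <= 1))
        assert np.all(np.diff(stats.mu) >= 0)

    def test_invariant_to_subset_order(self):
        training = self._subsets(6)
        reversed_training = type(training)(
            items=training.items[::-1], mode=training.mode, metric_id=training.metric_id
        )
        a = estimate_statistics(training, M=4)
        b = estimate_statistics(reversed_training, M=4)
        assert np.allclose(a.mu, b.mu)
        assert np.allclose(a.sigma, b.sigma)

    def test_too_few_subsets_rejected(self):
        with pytest.raises(ValidationError):
            self._subsets(2)

    def test_rank_deficiency_warns(self):
        with pytest.warns(UserWarning, match="rank deficient"):
            estimate_statistics(self._subsets(3, N=3), M=6)

    def test_roundtrip_serialisation_is_lossless(self, tmp_path):
        stats = estimate_statistics(self._subsets(6), M=4)
        path = tmp_path / "stats.cil"
        stats.save(path)
        loaded = CILStatistics.load(path)
        assert np.array_equal(loaded.mu, stats.mu)
        assert np.array_equal(loaded.sigma, stats.sigma)
        assert loaded.bins == stats.bins
        assert loaded.n_realisations == stats.n_realisations


class TestCilCost:
    def _stats(self, mu, sigma, bins=None):
        M = mu.size
        bins = bins or RadiusBins(np.arange(1.0, M + 1))
        return CILStatistics(mu=mu, sigma=sigma, bins=bins, n_realisations=100)

    def test_zero_residual_gives_zero(self):
        mu = np.linspace(0.1, 0.9, 4)
        stats = self._stats(mu, np.eye(4))
        y = ECDFVector(mu, stats.bins)
        assert cil_cost(y, stats) == pytest.approx(0.0)

    def test_identity_covariance_unit_residual(self):
        mu = np.array([0.2, 0.4, 0.6, 0.8])
        stats = self._stats(mu, np.eye(4))
        y = ECDFVector(mu + np.array([0.0, 0.0, 0.0, 0.1]), stats.bins)
        assert cil_cost(y, stats) == pytest.approx(0.01)

    def test_matches_dense_inverse_oracle(self):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(5, 5))
        sigma = A @ A.T + 0.5 * np.eye(5)
        mu = np.sort(rng.random(5))
        stats = self._stats(mu, sigma)
        y = ECDFVector(np.clip(np.sort(mu + 0.05 * rng.normal(size=5)), 0, 1), stats.bins)
        r = y.y - mu
        oracle = r @ np.linalg.inv(sigma) @ r
        assert cil_cost(y, stats) == pytest.approx(oracle, abs=1e-10)

    def test_bin_mismatch_rejected(self):
        mu = np.full(3, 0.5)
        stats = self._stats(mu, np.eye(3))
        other = ECDFVector(mu, RadiusBins(np.array([0.5, 1.0, 1.5])))
        with pytest.raises(ValidationError):
            cil_cost(other, stats)


class TestChi2Calibration:
    def test_chi2_sample_is_well_calibrated(self):
        costs = chi2(10).rvs(size=2000, random_state=np.random.default_rng(9))
        report = chi2_calibration(costs, 10)
        assert 0.9 <= report["mean_ratio"] <= 1.1
        assert report["ks_pvalue"] > 0.01

    def test_degenerate_zero_costs(self):
        report = chi2_calibration(np.zeros(100), 10)
        assert report["mean_ratio"] == 0.0
        assert report["ks_pvalue"] < 1e-10

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            chi2_calibration(np.ones(10), 5)


@pytest.fixture(scope="module")
def cost_setup(turing_theta, small_grid, quick_turing_cfg):
    """Cheap 1-D pattern configuration for stochastic cost evaluation."""

    def sim_items(theta, n, seed):
        ens = simulate_turing_ensemble(theta, small_grid, n, 0.01, seed, quick_turing_cfg)
        return pattern_items(ens)

    items = sim_items(turing_theta, 50, 42)
    training = partition_items(
        items, 10, 5, mode="pattern-subsets", cell_volume=small_grid.cell_volume
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stats = estimate_statistics(training, M=5)
    return sim_items, training, stats


class TestCostAtParameter:

    def test_reproducible_under_fixed_seed(self, cost_setup, turing_theta):
        sim_items, training, stats = cost_setup
        a = cil_cost_at_parameter(turing_theta, stats, sim_items, 5, training, seed=3)
        b = cil_cost_at_parameter(turing_theta, stats, sim_items, 5, training, seed=3)
        assert a == b and np.isfinite(a)

    def test_wrong_parameters_score_far_beyond_chi2_tail(self, cost_setup, turing_theta):
        # tenfold smaller inhibitor diffusion: no comparable patterns
        sim_items, training, stats = cost_setup
        far = turing_theta.replace_values(
            np.where(np.array(turing_theta.names) == "d_v", 4.0, turing_theta.values)
        )
        costs = [
            cil_cost_at_parameter(far, stats, sim_items, 5, training, seed=100 + r)
            for r in range(10)
        ]
        assert np.median(costs) > chi2(stats.bins.M).ppf(0.99)

    def test_scil_single_snapshot_returns_finite_cost(self, cost_setup, turing_theta, small_grid):
        sim_items, training, stats = cost_setup
        data = sim_items(turing_theta, 1, 777)  # a single observed pattern
        value = scil_cost(
            turing_theta, data, sim_items, N=5, n_ens_sim=8, seed=11,
            M=5, cell_volume=small_grid.cell_volume,
        )
        repeat = scil_cost(
            turing_theta, data, sim_items, N=5, n_ens_sim=8, seed=11,
            M=5, cell_volume=small_grid.cell_volume,
        )
        assert np.isfinite(value) and value >= 0
        assert value == repeat


def test_distance_and_ecdf_export_as_delimited_text(tmp_path):
    d = DistanceSample(np.array([0.5, 1.5, 2.5]), metric_id="L2")
    d.to_csv(tmp_path / "d.csv")
    assert np.allclose(np.loadtxt(tmp_path / "d.csv", skiprows=1), d.values)
    y = ecdf_patterns(d, RadiusBins(np.array([1.0, 2.0, 3.0])))
    y.to_csv(tmp_path / "y.csv")
    table = np.loadtxt(tmp_path / "y.csv", delimiter=",", skiprows=1)
    assert np.allclose(table[:, 1], y.y)


def test_partial_observation_through_component_mask(small_pattern_ensemble):
    full = pattern_items(small_pattern_ensemble)
    masked_ens = type(small_pattern_ensemble)(
        patterns=small_pattern_ensemble.patterns,
        grid_shape=small_pattern_ensemble.grid_shape,
        component_names=small_pattern_ensemble.component_names,
        component_mask=(True, False),
        cell_volume=small_pattern_ensemble.cell_volume,
        stationary=small_pattern_ensemble.stationary,
    )
    partial = pattern_items(masked_ens)
    assert partial.shape[1] == full.shape[1] // 2
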