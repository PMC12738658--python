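"""Langevin, SVGD and the 1-D Fokker-Planck reference solver."""

import numpy as np
import pytest

from cilkit.errors import GradientFailureError, TimeStepError, ValidationError
from cilkit.gradflow import (
    AnalyticPotential,
    DensityGrid1D,
    KernelSpec,
    ParticleEnsemble,
    fokker_planck_1d,
    grad_potential,
    kl_decay_monitor,
    kl_divergence_grids,
    langevin_sample,
    stationary_density,
    svgd_sample,
    svgd_step,
)


class TestGradPotential:
    def test_quadratic_is_exact_under_central_differences(self):
        V = lambda th: 0.5 * float(np.sum(np.asarray(th) ** 2))
        x = np.array([1.0, -2.0, 0.3])
        assert np.allclose(grad_potential(V, x), x, atol=1e-8)

    def test_matrix_quadratic_matches_analytic_2A_theta(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(3, 3))
        A = A @ A.T
        V = lambda th: float(th @ A @ th)
        x = rng.normal(size=3)
        assert np.allclose(grad_potential(V, x), 2.0 * A @ x, rtol=1e-6)

    def test_error_decays_quadratically_with_step(self):
        V = lambda th: float(th[0] ** 4)
        x = np.array([1.3])
        errors = [abs(grad_potential(V, x, h=h)[0] - 4 * 1.3**3) for h in (1e-2, 5e-3, 2.5e-3)]
        orders = np.log2(np.array(errors[:-1]) / np.array(errors[1:]))
        assert np.all(np.abs(orders - 2.0) < 0.5)

    def test_registered_analytic_gradient_takes_priority(self):
        V = AnalyticPotential(lambda th: 0.0, lambda th: np.full_like(th, 42.0))
        assert np.allclose(grad_potential(V, np.zeros(2)), 42.0)

    def test_non_finite_stencil_value_raises(self):
        V = lambda th: float("inf") if th[0] > 1.0 else 0.0
        with pytest.raises(GradientFailureError):
            grad_potential(V, np.array([1.0]))


class TestLangevin:
    def test_stationary_variance_matches_closed_form(self, std_normal_potential):
        # AR(1) recursion X' = (1-h)X + sqrt(2h) xi has variance 1/(1 - h/2)
        for h in (0.2, 0.1, 0.05):
            n_particles = 20_000
            burn = langevin_sample(
                std_normal_potential, np.zeros((n_particles, 1)), h, int(30 / h), seed=3
            )
            pooled = [burn.positions]
            state = burn.positions
            for k in range(4):
                step = langevin_sample(std_normal_potential, state, h, int(3 / h), seed=50 + k)
                state = step.positions
                pooled.append(state)
            var = np.concatenate(pooled).var(ddof=1)
            expected = 1.0 / (1.0 - h / 2.0)
            se = np.sqrt(2.0 / (n_particles * 2)) * expected  # conservative ESS
            assert abs(var - expected) < 4.0 * se

    def test_zero_noise_is_monotone_gradient_descent(self, std_normal_potential):
        x = np.array([[2.0]])
        values = []
        for _ in range(20):
            x = langevin_sample(std_normal_potential, x, 0.1, 1, seed=0, noise=False).positions
            values.append(float(std_normal_potential(x[0])))
        assert np.all(np.diff(values) < 0)

    def test_seeded_reproducibility(self, std_normal_potential):
        a = langevin_sample(std_normal_potential, np.zeros((10, 2)), 0.1, 50, seed=5)
        b = langevin_sample(std_normal_potential, np.zeros((10, 2)), 0.1, 50, seed=5)
        assert np.array_equal(a.positions, b.positions)

    def test_diverging_particles_flagged_and_frozen(self):
        # concave potential: gradient flow pushes particles to infinity
        V = AnalyticPotential(
            lambda x: -10.0 * float(np.sum(np.asarray(x) ** 4)),
            lambda x: -40.0 * np.asarray(x) ** 3,
            grad_batch=lambda p: -40.0 * np.asarray(p) ** 3,
        )
        with pytest.warns(UserWarning, match="diverged"), np.errstate(all="ignore"):
            ens = langevin_sample(V, np.full((5, 1), 2.0), 0.5, 200, seed=1)
        assert np.all(ens.diverged)
        assert np.all(np.isfinite(ens.positions))


class TestSvgd:
    def test_single_particle_reduces_to_scaled_gradient_descent(self, std_normal_potential):
        ens = ParticleEnsemble(positions=np.array([[1.5]]))
        out = svgd_step(ens, std_normal_potential, KernelSpec(bandwidth=2.0), dt=0.1)
        # K(0) = 1 and grad K(0) = 0: theta <- theta - dt * K(0) * grad V(theta)
        assert out.positions[0, 0] == pytest.approx(1.5 - 0.1 * 1.5)

    def test_coincident_particles_at_critical_point_are_stationary(self, std_normal_potential):
        ens = ParticleEnsemble(positions=np.zeros((5, 2)))
        out = svgd_step(ens, std_normal_potential, KernelSpec(bandwidth=1.0), dt=0.2)
        assert np.array_equal(out.positions, ens.positions)

    def test_two_particle_step_matches_hand_computed_dynamics(self, std_normal_potential):
        h = 2.0
        pos = np.array([[0.0], [1.0]])
        ens = ParticleEnsemble(positions=pos)
        out = svgd_step(ens, std_normal_potential, KernelSpec(bandwidth=h), dt=0.1)
        # brute-force evaluation of the interacting-particle ODE right side
        K = lambda z: np.exp(-z**2 / h)
        dK = lambda z: -2.0 * z / h * np.exp(-z**2 / h)
        vel = np.empty(2)
        for i in range(2):
            vel[i] = -0.5 * sum(dK(pos[i, 0] - pos[j, 0]) for j in range(2)) - 0.5 * sum(
                K(pos[i, 0] - pos[j, 0]) * pos[j, 0] for j in range(2)
            )
        assert np.allclose(out.positions[:, 0], pos[:, 0] + 0.1 * vel, atol=1e-12)

    def test_deterministic_bit_for_bit(self, std_normal_potential):
        init = np.random.default_rng(2).normal(2.0, 0.5, size=(50, 1))
        a = svgd_sample(std_normal_potential, init.copy(), n_steps=200)
        b = svgd_sample(std_normal_potential, init.copy(), n_steps=200)
        assert np.array_equal(a.positions, b.positions)

    def test_mean_converges_to_target_mean(self, std_normal_potential):
        init = np.random.default_rng(0).normal(2.0, 0.5, size=(100, 1))
        final = svgd_sample(std_normal_potential, init, dt=0.1, n_steps=1500)
        assert abs(final.positions.mean()) < 0.05

    def test_non_positive_bandwidth_rejected(self):
        with pytest.raises(ValidationError):
            KernelSpec(bandwidth=-1.0)


@pytest.fixture(scope="module")
def fp_setup(std_normal_potential):
    nodes = np.linspace(-12.0, 12.0, 481)
    rho0 = DensityGrid1D.from_unnormalised(nodes, np.exp(-(nodes**2) / 8.0))  # sigma0 = 2
    return std_normal_potential, nodes, rho0


class TestFokkerPlanck:
    def test_mass_conserved_along_the_flow(self, fp_setup):
        V, nodes, rho0 = fp_setup
        _, densities = fokker_planck_1d(V, rho0, dt=1e-3, T=2.0, store_every=200)
        masses = [np.trapezoid(d.values, nodes) for d in densities]
        assert max(abs(m - 1.0) for m in masses) < 1e-8

    def test_discrete_boltzmann_density_is_stationary(self, fp_setup):
        V, nodes, _ = fp_setup
        rho_inf = stationary_density(V, nodes)
        _, densities = fokker_planck_1d(V, rho_inf, dt=1e-3, T=1.0, store_every=1000)
        assert np.abs(densities[-1].values - rho_inf.values).max() < 1e-6

    def test_variance_follows_ornstein_uhlenbeck_law(self, fp_setup):
        V, nodes, rho0 = fp_setup
        times, densities = fokker_planck_1d(V, rho0, dt=1e-3, T=2.0, store_every=200)
        for t, d in zip(times, densities):
            var = np.trapezoid(d.values * nodes**2, nodes)
            assert var == pytest.approx(1.0 + 3.0 * np.exp(-2.0 * t), abs=5e-3)

    def test_cfl_violation_raises_with_suggested_step(self, fp_setup):
        V, nodes, rho0 = fp_setup
        with pytest.raises(TimeStepError) as err:
            fokker_planck_1d(V, rho0, dt=0.1, T=1.0)
        assert err.value.suggested_dt is not None
        assert err.value.suggested_dt < 0.1

    def test_kl_to_target_decays_monotonically(self, fp_setup):
        V, nodes, rho0 = fp_setup
        traj = fokker_planck_1d(V, rho0, dt=1e-3, T=2.0, store_every=100)
        kls = kl_decay_monitor(traj, V)
        assert np.all(np.diff(kls) <= 1e-8)
        assert kls[-1] < kls[0]

    def test_stationary_start_gives_constant_zero_kl(self, fp_setup):
        V, nodes, _ = fp_setup
        rho_inf = stationary_density(V, nodes)
        traj = fokker_planck_1d(V, rho_inf, dt=1e-3, T=0.5, store_every=100)
        kls = kl_decay_monitor(traj, V)
        assert np.all(np.abs(kls) < 1e-10)


class TestKlDivergence:
    def test_identical_densities_give_zero(self, fp_setup):
        _, nodes, rho0 = fp_setup
        assert kl_divergence_grids(rho0, rho0) == 0.0

    def test_shifted_gaussians_match_closed_form(self):
        nodes = np.linspace(-10.0, 11.0, 2101)
        p = DensityGrid1D.from_unnormalised(nodes, np.exp(-(nodes**2) / 2.0))
        q = DensityGrid1D.from_unnormalised(nodes, np.exp(-((nodes - 1.0) ** 2) / 2.0))
        assert kl_divergence_grids(p, q) == pytest.approx(0.5, abs=1e-3)

    def test_nonnegative_on_random_density_pairs(self):
        rng = np.random.default_rng(6)
        nodes = np.linspace(0.0, 1.0, 200)
        for _ in range(10):
            p = DensityGrid1D.from_unnormalised(nodes, rng.random(200) + 0.05)
            q = DensityGrid1D.from_unnormalised(nodes, rng.random(200) + 0.05)
            assert kl_divergence_grids(p, q) >= 0.0

    def test_absolute_continuity_violation_returns_inf(self):
        nodes = np.linspace(0.0, 1.0, 101)
        p = DensityGrid1D.from_unnormalised(nodes, np.ones(101))
        qv = np.ones(101)
        qv[50] = 0.0
        q = DensityGrid1D.from_unnormalised(nodes, qv)
        with pytest.warns(UserWarning, match="absolute continuity"):
            assert kl_divergence_grids(p, q) == np.inf


def test_langevin_particles_agree_with_fokker_planck_density(std_normal_potential):
    """Histogram of Langevin particles vs the PDE density in total variation."""
    nodes = np.linspace(-12.0, 12.0, 481)
    rho0 = DensityGrid1D.from_unnormalised(nodes, np.exp(-((nodes - 2.0) ** 2) / 2.0))
    _, densities = fokker_planck_1d(std_normal_potential, rho0, dt=1e-3, T=5.0, store_every=5000)
    pde = densities[-1]

    h = 0.01
    init = 2.0 + np.random.default_rng(8).standard_normal((1000, 1))
    particles = langevin_sample(std_normal_potential, init, h, int(5.0 / h), seed=9)

    edges = np.linspace(-6.0, 6.0, 25)
    hist, _ = np.histogram(particles.positions[:, 0], bins=edges, density=True)
    centers = (edges[:-1] + edges[1:]) / 2.0
    pde_on_bins = np.interp(centers, nodes, pde.values)
    width = edges[1] - edges[0]
    tv = 0.5 * np.sum(np.abs(hist - pde_on_bins)) * width
    assert tv <= 0.1
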