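import numpy as np
import pytest

from cilkit.forward_models import (
    ParameterVector,
    TuringGrid,
    TuringSolverConfig,
    schnakenberg_default_theta,
    simulate_turing_ensemble,
)
from cilkit.gradflow import AnalyticPotential


@pytest.fixture(scope="session")
def turing_theta():
    return schnakenberg_default_theta()


@pytest.fixture(scope="session")
def small_grid():
    """Cheap 1-D grid for structural tests (not for calibration)."""
    return TuringGrid((48,), 50.0)


@pytest.fixture(scope="session")
def quick_turing_cfg():
    return TuringSolverConfig(dt=0.25, t_max=80.0)


@pytest.fixture(scope="session")
def small_pattern_ensemble(turing_theta, small_grid, quick_turing_cfg):
    return simulate_turing_ensemble(turing_theta, small_grid, 12, 0.01, 11, quick_turing_cfg)


@pytest.fixture(scope="session")
def std_normal_potential():
    """V(theta) = |theta|^2 / 2 with analytic (batched) gradient."""
    return AnalyticPotential(
        lambda x: 0.5 * float(np.sum(np.asarray(x, dtype=float) ** 2)),
        lambda x: np.asarray(x, dtype=float),
        grad_batch=lambda p: np.asarray(p, dtype=float),
    )
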