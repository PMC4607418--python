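import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from drupemc import SimulationConfig, baseline_stack, run_simulation
from drupemc.experiments import FLESH_OPTICS_GRID

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


class StubRng:
    """Deterministic stand-in for a Generator: returns queued values."""

    def __init__(self, values):
        self._values = list(values)

    def random(self):
        return self._values.pop(0)


@pytest.fixture
def rng():
    return np.random.default_rng(20150902)


@pytest.fixture
def stub_rng():
    return StubRng


@pytest.fixture(scope="session")
def optics_grid_runs():
    """One moderate run per flesh (mu_a, mu_s) pair of the standard grid.

    Shared session-wide: the energy-budget comparisons, the monotonic
    ordering checks and the detection-metric trends all read these.
    """
    runs = {}
    for i, (mua, mus) in enumerate(FLESH_OPTICS_GRID):
        cfg = SimulationConfig(n_photons=200_000, seed=1000 + i)
        runs[(mua, mus)] = run_simulation(
            baseline_stack(flesh_mua=mua, flesh_mus=mus), cfg
        )
    return runs


@pytest.fixture(scope="session")
def core_comparison_runs():
    """Stone (n_below=1.46) vs air-backed (1.00) flesh at d2 = 1.5 cm.

    The reflectance gap between the two is a few parts per thousand, so the
    ordering checks need ~1e6 photons for a 3-sigma separation.
    """
    runs = {}
    for seed, nb in ((41, 1.00), (42, 1.46)):
        cfg = SimulationConfig(n_photons=1_000_000, seed=seed)
        runs[nb] = run_simulation(baseline_stack(d2=1.5, n_below=nb), cfg)
    return runs


@pytest.fixture(scope="session")
def baseline_run(optics_grid_runs):
    """The mean-coefficient member of the grid (skin 0.03 cm, flesh 2.0 cm)."""
    return optics_grid_runs[(0.024, 28.4)]
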