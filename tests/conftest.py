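import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from admixprec.datatypes import SimulationConfig
from admixprec.simulate import simulate_individuals, simulate_reference

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_trihybrid():
    """Small trihybrid world shared by read-only tests: refs + cohort + truth."""
    cfg = SimulationConfig(L=60, seed=1234)
    sim = simulate_reference(cfg)
    cohort, true_q = simulate_individuals(
        sim.true_freqs, n=30, dirichlet_alpha=cfg.dirichlet_alpha, seed=4321
    )
    return cfg, sim, cohort, true_q


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
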