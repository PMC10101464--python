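import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from coliphagenet.simulate import SimConfig, simulate

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_default():
    """One default-parameter cohort shared across tests (read-only)."""
    return simulate(SimConfig(seed=0))


@pytest.fixture(scope="session")
def planted_cfg():
    """Planted-family recovery conditions: 3 families x 3 single-gene modules,
    5 genomes each, 3% per-site divergence, no mosaicism."""
    return SimConfig(
        n_families=3,
        modules_per_family=3,
        genes_per_module=1,
        genomes_per_family=5,
        mosaicism_rate=0.0,
        mutation_rate=0.03,
        gene_length=600,
        seed=0,
    )


@pytest.fixture(scope="session")
def planted_sim(planted_cfg):
    return simulate(planted_cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
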