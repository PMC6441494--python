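import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cico.synthetic_data import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def bundle_nb():
    """Default synthetic bundle (NB noise) at seed 1."""
    return generate_dataset(SimConfig(), seed=1)


@pytest.fixture(scope="session")
def bundle_noiseless():
    """Default design with noiseless counts at seed 1."""
    return generate_dataset(SimConfig(noise="none"), seed=1)


@pytest.fixture(scope="session")
def small_bundle():
    """Scaled-down bundle for fast unit tests."""
    config = SimConfig(
        n_chroms=1, chrom_length=200_000, n_genes=60, n_circ=30,
        library_size=12_000, n_mirnas=6, n_seed_circs=3, n_orf_circs=3,
        noise="none",
    )
    return generate_dataset(config, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
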