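import numpy as np
import pytest

from wustat.simulate import SimConfig, simulate_study

FIXTURE_DIR = "tests/data/synthetic_study"

# configuration of the small committed synthetic study used by fast tests
SMALL_CONFIG = SimConfig(
    n=30, n_genes=5, n_causal=2, snvs_per_gene=(8, 20), seed=20_240_101
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """In-memory copy of the committed 30-sample, 5-gene synthetic study."""
    return simulate_study(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_study_dir(tmp_path_factory):
    """The same study written out in the on-disk formats the readers consume."""
    out = tmp_path_factory.mktemp("study")
    simulate_study(SMALL_CONFIG, out)
    return out
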