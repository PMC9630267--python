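import numpy as np
import pytest
from hypothesis import settings

from xprio.features import assemble_feature_table
from xprio.synth import SynthConfig, generate_universe

settings.register_profile("default", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_universe():
    """A 300-gene synthetic universe shared by the integration tests."""
    return generate_universe(SynthConfig(n_genes=300, seed=11))


@pytest.fixture(scope="session")
def small_features(small_universe):
    """The assembled 83-column feature table of the small universe."""
    return assemble_feature_table(small_universe.feature_inputs())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
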