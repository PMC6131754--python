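import numpy as np
import pytest

from enhancer_rewire.synthetic_data import ScenarioConfig, simulate


@pytest.fixture(scope="session")
def default_dataset():
    """The default scenario: 2%/42%/56% FCE/RPE/EG, no sequence divergence."""
    return simulate(ScenarioConfig(seed=11))


@pytest.fixture(scope="session")
def diverged_dataset():
    """Default category mix with substitutions and indels switched on."""
    return simulate(
        ScenarioConfig(seed=12, substitution_rate=0.05, indel_rate=0.01)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(202409)
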