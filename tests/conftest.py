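import numpy as np
import pytest

from radassoc.params import DEFAULT_SCENARIO, MODEL_PRESETS


@pytest.fixture(scope="session")
def models():
    return MODEL_PRESETS


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def small_scenario():
    """Default exposure scenario scaled down to a quick cohort."""
    return DEFAULT_SCENARIO.replace(n_persons=2000, n_runs=2, base_seed=99)
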