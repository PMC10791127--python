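import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def trajectory_pool():
    """Small shared set of admissible trajectory pairs (seeded)."""
    from huetrack import make_trial_pairs

    return make_trial_pairs(30, rng=np.random.default_rng(1234))


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
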