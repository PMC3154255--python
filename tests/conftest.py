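import numpy as np
import pytest
from hypothesis import settings

from depscreen import default_paramset

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def base_params():
    """Base-case parameter set (published values + synthetic default curves)."""
    return default_paramset()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
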