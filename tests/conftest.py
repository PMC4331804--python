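import numpy as np
import pytest

from nfapin.synthetic import gen_benchmark


@pytest.fixture
def rng():
    return np.random.default_rng(20150129)


@pytest.fixture(scope="session")
def benchmark():
    """Default planted-module benchmark, one instance per session."""
    return gen_benchmark(seed=7)
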