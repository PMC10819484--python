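import numpy as np
import pytest

from rhizoquant import SyntheticRootSpec, generate


@pytest.fixture(scope="session")
def default_fixture():
    """One default synthetic micrograph with its ground truth."""
    return generate(SyntheticRootSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240114)
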