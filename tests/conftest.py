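import numpy as np
import pytest

from femi.simulate import make_fixture


@pytest.fixture(scope="session")
def tiny_sim():
    return make_fixture("tiny-2country", seed=11)


@pytest.fixture(scope="session")
def scheme_sim():
    return make_fixture("scheme-change", seed=5)


@pytest.fixture(scope="session")
def missing_sim():
    return make_fixture("missing-domain", seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
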