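import numpy as np
import pytest

from quasimodes.networks import NetworkSpec, jacobian


@pytest.fixture(scope="session")
def spec3():
    """Rock-paper-scissors regime with a single resonant mode."""
    return NetworkSpec(n=3, r=1.0, alpha=0.1, beta=0.1)


@pytest.fixture(scope="session")
def spec5():
    """Five-species network in the two-resonance regime."""
    return NetworkSpec(n=5, r=4.0, alpha=0.01, beta=0.01)


@pytest.fixture(scope="session")
def J3(spec3):
    return jacobian(spec3)


@pytest.fixture(scope="session")
def J5(spec5):
    return jacobian(spec5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20251201)
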