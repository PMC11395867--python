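import numpy as np
import pytest

from fraclung import reference_scenario


@pytest.fixture(scope="session")
def base_scenario():
    """Untreated reference scenario (initial state 1.5, 0.7, 0.3, 0.1, 0.1)."""
    return reference_scenario("base-A")


@pytest.fixture(scope="session")
def optimal_scenario():
    """Default optimal-dosing scenario (initial state 5, 1, 1, 1, 1, Tf = 3)."""
    return reference_scenario("optimal-C")


@pytest.fixture(scope="session")
def pid_scenario():
    """Default closed-loop scenario (initial state 2, 3, 1, 1, 1, Tf = 3)."""
    return reference_scenario("pid-D")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
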