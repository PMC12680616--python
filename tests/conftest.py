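import numpy as np
import pytest

from glucid import glucose_ode


@pytest.fixture(scope="session")
def small_type2_dataset():
    """Type-2 scenario at reduced segment length: 200 rows, split 140/60."""
    return glucose_ode.build_dataset(glucose_ode.scenario("type2", 50))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
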