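import numpy as np
import pytest

from ringising import IsingParameters, build_arrangements, build_patterns


@pytest.fixture(scope="session")
def patterns():
    return build_patterns()


@pytest.fixture(scope="session")
def arrangements():
    return build_arrangements()


@pytest.fixture(scope="session")
def study_params():
    """Headline pure-sample parameters (J, B_AA, B_EE)."""
    return IsingParameters(J=0.14, B_AA=0.19, B_EE=-0.25)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
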