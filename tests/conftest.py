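import numpy as np
import pytest

from proteokin.models import build_model
from proteokin.synthetic import fixture_parameters


@pytest.fixture(scope="session")
def m9():
    return build_model("M9")


@pytest.fixture(scope="session")
def llvy():
    return fixture_parameters("LLVY")


@pytest.fixture(scope="session")
def lle():
    return fixture_parameters("LLE")


@pytest.fixture(scope="session")
def kinetics_times():
    return np.arange(5.0, 365.0, 5.0)
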