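import numpy as np
import pytest

from hemosplit import (
    SynthConfig,
    default_extinction_table,
    generate_session,
    standard_designs,
)


@pytest.fixture(scope="session")
def finger_design():
    return standard_designs("finger_tapping")


@pytest.fixture(scope="session")
def tilt_design():
    return standard_designs("tilt_or_breathhold")


@pytest.fixture(scope="session")
def extinction():
    return default_extinction_table()


@pytest.fixture(scope="session")
def default_session(finger_design):
    """One default finger-tapping session with stored ground truth."""
    return generate_session(finger_design, SynthConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
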