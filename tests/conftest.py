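import numpy as np
import pytest
from hypothesis import settings

import opmcal as oc

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def helmet_slots():
    return oc.make_helmet_slots(seed=11)


@pytest.fixture(scope="session")
def small_array(helmet_slots):
    """16-sensor / 48-channel array with realistic defects and noise."""
    return oc.make_synthetic_array(helmet_slots, n_sensors=16, seed=12)


@pytest.fixture(scope="session")
def quiet_small_array(helmet_slots):
    """16-sensor array with zero sensor noise (closed-loop exactness tests)."""
    return oc.make_synthetic_array(helmet_slots, n_sensors=16,
                                   noise_density=0.0, seed=13)


@pytest.fixture(scope="session")
def full_array():
    """The study-condition 128-sensor / 384-channel array."""
    return oc.default_array(seed=1)


@pytest.fixture(scope="session")
def phantom():
    return oc.make_phantom()
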