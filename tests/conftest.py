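import numpy as np
import pytest

from circaretina.stimulus import build_flash_protocol
from circaretina.synthetic import simulate_session


@pytest.fixture(scope="session")
def protocol():
    """Standard full protocol: 4 contrast blocks, 20 trials each."""
    return build_flash_protocol()


@pytest.fixture(scope="session")
def ct100_protocol():
    """Lean protocol with only the maximum-contrast block."""
    return build_flash_protocol(contrasts=[100.0])


@pytest.fixture(scope="session")
def small_session(ct100_protocol):
    """A small simulated retina with ground truth (seeded)."""
    counts = {"ON_sust": 6, "ON_trans": 6, "OFF_sust": 4, "OFF_trans": 4, "ONOFF": 6}
    return simulate_session(
        counts=counts, protocol=ct100_protocol, seed=42, retina_id="fix"
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
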