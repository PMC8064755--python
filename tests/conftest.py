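import numpy as np
import pytest

from filaclock.params import default_params


@pytest.fixture(scope="session")
def fitted_params():
    """The fitted single-clock parameter point (stable focus near the Hopf
    boundary)."""
    return default_params()


@pytest.fixture(scope="session")
def circadian_focus_params():
    """A more damped stable focus whose quasi-cycle period is circadian
    (~24.7 hr); used where linear-noise accuracy matters."""
    return default_params(gamma=5.0, kaiA_total=1.3)


@pytest.fixture(scope="session")
def limit_cycle_params():
    """A parameter point inside the deterministic oscillation region with a
    circadian period (~23.9 hr)."""
    return default_params(gamma=12.0, kaiA_total=1.4)
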