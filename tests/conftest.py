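import numpy as np
import pytest

from farkit.phantom import AcquisitionSettings, InjectionRecord, TumourFocus, make_specimen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_settings():
    """Acquisition settings with gamma strikes disabled, for deterministic tests."""
    return AcquisitionSettings(gamma_strike_rate=0.0)


@pytest.fixture
def superior_specimen():
    """Specimen with a single surface focus in the superior sector."""
    return make_specimen(foci=[TumourFocus(center_xy=(0.0, 11.0), radius=3.0)])


@pytest.fixture
def record():
    return InjectionRecord(injected_activity=242.0, minutes_post_injection=145.0)
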