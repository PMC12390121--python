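import pytest

from beefdam import default_profile
from beefdam.scenarios import GenericScenarioSpec, build_generic


@pytest.fixture
def profile():
    return default_profile()


@pytest.fixture
def generic_270():
    """The constant-ration lifetime scenario at 0.270 ug/kg, slaughter day 540."""
    return build_generic(GenericScenarioSpec(ration_conc=0.270, slaughter_day=540))
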