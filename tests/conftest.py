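import pytest
from hypothesis import settings

from igpbpk import load_physiology

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from igpbpk.calibrate import setup_context


@pytest.fixture(scope="session")
def human_phys():
    return load_physiology("human")


@pytest.fixture(scope="session")
def monkey_phys():
    return load_physiology("monkey")


@pytest.fixture(scope="session")
def ctx(monkey_phys, human_phys):
    """Calibrated two-species translation context (expensive; built once)."""
    return setup_context(monkey_phys, human_phys)
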