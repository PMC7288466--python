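import pytest
from hypothesis import settings

from orimin import GrowthModel, PhaseDurations

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture
def growth24() -> GrowthModel:
    return GrowthModel(doubling_time=24.0)


@pytest.fixture
def epimastigote_like() -> PhaseDurations:
    """Phase set matching the trypanosomatid with the 24 h cycle."""
    return PhaseDurations(g1=5.91, s=9.86, g2=1.25, m=0.75, c=6.23)
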