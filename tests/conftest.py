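import pytest

from scarbayes import ArmCounts, HistoricalTrial
from scarbayes.datasets import (
    current_trial,
    historical_trials,
    huang_2011,
    shaikh_2020_reconstructed,
)


@pytest.fixture
def huang() -> HistoricalTrial:
    return huang_2011()


@pytest.fixture
def shaikh() -> HistoricalTrial:
    return shaikh_2020_reconstructed()


@pytest.fixture
def both_trials() -> list[HistoricalTrial]:
    return historical_trials()


@pytest.fixture
def observed():
    """Realized primary-outcome counts: 0/7 treated vs 2/11 control."""
    return current_trial()
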