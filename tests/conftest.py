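import numpy as np
import pytest
from hypothesis import settings

from respirhythm import ChamberSpec, FishLot, PhotoperiodSchedule

settings.register_profile("deterministic", derandomize=True, max_examples=25)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fish():
    """Five juveniles: total 0.0025 kg / 0.005 L, the worked-example geometry."""
    return FishLot()


@pytest.fixture(scope="session")
def chamber():
    return ChamberSpec()


@pytest.fixture(scope="session")
def schedule():
    return PhotoperiodSchedule()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
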