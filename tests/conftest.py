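import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from csra.plates import DosePlate, LADDER
from csra.synthetic import gen_table4_fixture

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table4():
    """The published 37-specimen cohort rebuilt from its summary tables."""
    return gen_table4_fixture()


def make_plate(
    inhibitions,
    specimen="S1",
    drug="Dox",
    vehicle=1000.0,
    blank=100.0,
    replicates=1,
):
    """Build a noiseless plate whose normalized inhibition equals `inhibitions`."""
    window = vehicle - blank
    treated = {
        frac: [blank + window * (1.0 - inh / 100.0)] * replicates
        for frac, inh in zip(LADDER, inhibitions)
    }
    return DosePlate(
        specimen_id=specimen,
        drug=drug,
        treated_signals=treated,
        vehicle_signals=[vehicle] * 3,
        blank_signals=[blank] * 3,
    )


@pytest.fixture
def plate_factory():
    return make_plate


@pytest.fixture
def rng():
    return np.random.default_rng(20220401)
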