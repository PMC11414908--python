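import numpy as np
import pytest

from packetcode.events import apply_blanking
from packetcode.histograms import post_eod_histogram
from packetcode.simulate import simulate_population


@pytest.fixture(scope="session")
def cohort():
    """Mid-size six-archetype cohort (8 units/type, 500 EODs), blanked."""
    units = simulate_population(n_per_type=8, n_eods=500, seed=11)
    for u in units:
        u.spikes = apply_blanking(u.spikes, u.eods)
    return units


@pytest.fixture(scope="session")
def cohort_histograms(cohort):
    return {u.unit_id: post_eod_histogram(u.spikes, u.eods) for u in cohort}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
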