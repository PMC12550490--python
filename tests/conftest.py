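import numpy as np
import pytest

from paleoterrapin.discretize import TimeDiscretization
from paleoterrapin.synthdata import DemographyScenario, simulate_het_track


@pytest.fixture(scope="session")
def tiny_disc() -> TimeDiscretization:
    """Three atomic intervals, one free parameter each — oracle-sized."""
    return TimeDiscretization(n_atomic=3, pattern="1+1+1", t_max=2.0)


@pytest.fixture(scope="session")
def default_disc() -> TimeDiscretization:
    return TimeDiscretization()


@pytest.fixture(scope="session")
def constant_ne_sim():
    """Small constant-Ne diploid simulation shared across tests."""
    scen = DemographyScenario(
        epochs=[(0.0, 10_000.0)],
        mutation_rate_per_site_per_gen=1e-8,
        recombination_rate_per_site_per_gen=1e-8,
        sequence_length_bp=1_000_000,
        seed=11,
    )
    return simulate_het_track(scen)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
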