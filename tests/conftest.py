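import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")

from eidermoult.growth import fit_cohort
from eidermoult.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default 13-bird crossover cohort, fixed seed."""
    return simulate_cohort(SimConfig(seed=42))


@pytest.fixture(scope="session")
def default_fits(default_cohort):
    return fit_cohort(default_cohort["feather_measurements"])
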