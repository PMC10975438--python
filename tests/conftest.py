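import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cinnaprint as cp
from cinnaprint.simulate import generate_cohort, species_profiles_from_table

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_table():
    """The bundled 48-sample x 16-metabolite reference concentration table."""
    return cp.load_concentration_table()


@pytest.fixture(scope="session")
def profiles(ref_table):
    return species_profiles_from_table(ref_table)


@pytest.fixture(scope="session")
def quiet_params():
    """Noise-free default acquisition parameters."""
    return cp.SimulationParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def cohort30(profiles):
    """30-sample cohort (10 per species) at default noise, fixed seed."""
    return generate_cohort(profiles, 10, cp.SimulationParams(), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_spectrum(rng, n=4096, lo=-0.5, hi=12.5):
    """A rough random spectrum covering the full bucketing range."""
    ppm = np.linspace(lo, hi, n)
    intensity = rng.normal(0.0, 1.0, n) + np.abs(rng.normal(0, 5, n))
    return cp.Spectrum(ppm, intensity)
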