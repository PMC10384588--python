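import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vaspipe.constants import KB
import vaspipe as vp

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: temperature at which kB*T = 1 (reduced units)
REDUCED_T = 1.0 / KB


@pytest.fixture(scope="session")
def water_params():
    return vp.water_preset()


@pytest.fixture(scope="session")
def mixture_params():
    return vp.mixture_preset()


@pytest.fixture(scope="session")
def band_freq():
    """Log grid over the measurement band, Hz."""
    return np.logspace(np.log10(50.0), np.log10(3000.0), 40)


@pytest.fixture(scope="session")
def water_spectrum(water_params, band_freq):
    D = vp.eval_water_vas(2 * np.pi * band_freq, water_params)
    return vp.VelocitySpectrum(freq=band_freq, D=D, label="water model")


@pytest.fixture(scope="session")
def mixture_spectrum(mixture_params, band_freq):
    D = vp.eval_mixture_vas(2 * np.pi * band_freq, mixture_params)
    return vp.VelocitySpectrum(freq=band_freq, D=D, label="mixture model")
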