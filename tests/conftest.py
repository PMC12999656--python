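import math

import pytest

from thermoevo import DemographyParams, InvasionConfig, ThermalRegime


@pytest.fixture(scope="session")
def demo():
    return DemographyParams()


@pytest.fixture(scope="session")
def fig2a_regime():
    """Low-noise reference regime of the vector-field analysis."""
    return ThermalRegime(tau0=0.5, m=0.25, omega=13 * math.pi / 20, sigma_eps=0.5)


@pytest.fixture(scope="session")
def fig2b_regime():
    """High-noise reference regime."""
    return ThermalRegime(tau0=0.5, m=0.25, omega=13 * math.pi / 20, sigma_eps=1.5)


@pytest.fixture(scope="session")
def cfg_small():
    """Short averaging horizon for fast tests."""
    return InvasionConfig(horizon_L=20_000, burn_in=1000, noise_seed=11)
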