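import numpy as np
import pytest

from dcskit import OpticalProperties


@pytest.fixture(scope="session")
def phantom_optics() -> OpticalProperties:
    """Optical properties of the diluted-milk phantom at 785 nm."""
    return OpticalProperties(mu_a=0.0025, mu_s_prime=1.0, n0=1.33, wavelength_nm=785.0)


@pytest.fixture(scope="session")
def log_tau() -> np.ndarray:
    """Logarithmic lag grid spanning the phantom decay."""
    return np.logspace(-9, -2, 140)
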