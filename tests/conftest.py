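import numpy as np
import pytest

from cmrsi.encoding import make_aw_scheme, make_central_scheme
from cmrsi.phantom import PhantomConfig, make_cardiac_phantom
from cmrsi.recon import CompartmentMask

DWELL = 2.0e-4


@pytest.fixture(scope="session")
def phantom():
    """Default field-homogeneous cardiac phantom on the acquisition grid."""
    return make_cardiac_phantom()


@pytest.fixture(scope="session")
def mask(phantom):
    return CompartmentMask.from_phantom(phantom)


@pytest.fixture(scope="session")
def aw_scheme():
    return make_aw_scheme((8, 16, 8), 4)


@pytest.fixture(scope="session")
def central_scheme():
    return make_central_scheme((8, 16, 8), (4, 4, 4), 6)


@pytest.fixture(scope="session")
def inhomogeneous_phantom():
    """Phantom with smooth B0/phase inhomogeneity (study-like conditions)."""
    return make_cardiac_phantom(PhantomConfig(b0_peak_hz=20.0, phase_peak_rad=0.2))


def compartment_ground_truth(phantom, compartment, n_time, dwell_s=DWELL):
    """Independent oracle: closed-form compartment FID (sum of Lorentzians)."""
    t = np.arange(n_time) * dwell_s
    out = np.zeros(n_time, dtype=complex)
    for r in phantom.resonances[compartment]:
        out += (
            r.amplitude
            * np.exp(1j * r.phase_rad)
            * np.exp((2j * np.pi * r.frequency_hz - np.pi * r.linewidth_hz) * t)
        )
    return out
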