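import numpy as np
import pytest

from oxiraman.bands import GaussianBand, default_band_library
from oxiraman.synthetic import generate_pure_spectrum


@pytest.fixture(scope="session")
def library():
    return default_band_library()


@pytest.fixture(scope="session")
def oxo_dgtp_noiseless():
    """Pure 8-oxo-dGTP fingerprint spectrum, zero baseline, no noise."""
    return generate_pure_spectrum("8-oxo-dGTP", noise_sd=0.0)


@pytest.fixture(scope="session")
def dgtp_noiseless():
    return generate_pure_spectrum("dGTP", noise_sd=0.0)


@pytest.fixture
def single_band_spectrum():
    """One exact Gaussian at 1000 cm-1 (sigma 8, area 2) on a fine grid."""
    from oxiraman.spectra import Spectrum

    band = GaussianBand(1000.0, 8.0, 2.0)
    wn = np.arange(900.0, 1100.0 + 0.25, 0.25)
    return band, Spectrum(wavenumbers=wn, intensities=band.profile(wn))
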