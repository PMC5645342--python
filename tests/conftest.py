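import numpy as np
import pytest

from shgspec.dispersion import water
from shgspec.shg_model import GridSpec, build_profile

#: excitation band used throughout: 0.76-1.0 um in 20 nm steps
BAND_UM = np.round(np.arange(0.76, 1.0001, 0.02), 4)


@pytest.fixture(scope="session")
def water_model():
    return water()


@pytest.fixture(scope="session")
def default_grid():
    return GridSpec()


@pytest.fixture(scope="session")
def hamming_profile():
    """0.45 um Hamming-apodized fibre (myosin-like reference structure)."""
    return build_profile("hamming", 0.45, 0.23)


@pytest.fixture(scope="session")
def tophat_profile():
    """0.5 um top-hat fibre (collagen-like reference structure)."""
    return build_profile("tophat", 0.5, 0.23)
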