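import pytest

from twaspme.geometry import GridResolution
from twaspme.materials import BUILTIN_ANALYTES, BUILTIN_COATINGS


@pytest.fixture
def benzene():
    return BUILTIN_ANALYTES["benzene"]


@pytest.fixture
def car_pdms():
    return BUILTIN_COATINGS["car_pdms"]


@pytest.fixture
def pdms():
    return BUILTIN_COATINGS["pdms"]


@pytest.fixture
def fast_resolution():
    """Coarse grid for quick end-to-end plumbing tests (not accuracy)."""
    return GridResolution(
        n_radial_core=3,
        n_radial_coating=5,
        radial_gap_cell=60e-6,
        axial_cell_size=1.0e-3,
    )
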