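import numpy as np
import pytest

from mahm.grid import AcquisitionGrid
from mahm.phantom import (
    Compartment,
    TissueProfile,
    default_grid,
    default_profiles,
    make_phantom,
    two_region_spec,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def grid33():
    return AcquisitionGrid((47.0, 75.0, 100.0), (0.0, 750.0, 1500.0))


@pytest.fixture
def grid44():
    return default_grid()


@pytest.fixture
def mono_profile():
    """Single-compartment tissue: perfectly separable TE/b decay."""
    return TissueProfile(
        "mono", (Compartment(1.0, 100.0, 1.0e-3, "water"),), base_amplitude=1000.0
    )


def two_compartment(f_minor: float) -> TissueProfile:
    """Major compartment plus a minor one with distinct (T2, D)."""
    return TissueProfile(
        "duo",
        (
            Compartment(1.0 - f_minor, 60.0, 0.8e-3, "epithelium"),
            Compartment(f_minor, 600.0, 2.8e-3, "lumen"),
        ),
        base_amplitude=1000.0,
    )


@pytest.fixture
def noiseless_phantom(grid33):
    """Two-region noiseless phantom on a native 3x3 grid."""
    spec = two_region_spec(
        shape=(12, 12), roi_size=4, grid=grid33, snr=None, seed=7,
        profiles=default_profiles(),
    )
    return make_phantom(spec)
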