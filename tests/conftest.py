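import numpy as np
import pytest

from hepatofat.synthetic import gre_protocol, ideal_protocol


@pytest.fixture(scope="session")
def gre():
    return gre_protocol()


@pytest.fixture(scope="session")
def ideal():
    return ideal_protocol()


def forward_voxel(rho_w, rho_f, phi_hz, r2star, times_s, fat_shift_hz=217.0):
    """Closed-form single-voxel signal model, independent of the package's
    array-based forward evaluation; used as the round-trip oracle."""
    times_s = np.asarray(times_s, dtype=float)
    fat = np.exp(-1j * 2 * np.pi * fat_shift_hz * times_s)
    return (rho_w + rho_f * fat) * np.exp((-1j * 2 * np.pi * phi_hz - r2star) * times_s)


@pytest.fixture(scope="session")
def voxel_model():
    return forward_voxel
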