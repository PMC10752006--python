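import numpy as np
import pytest

from dbsimri import (
    FiberComponent,
    IsotropicSpectrum,
    VoxelModel,
    forward_signal,
    make_scheme,
)


@pytest.fixture(scope="session")
def invivo_scheme():
    return make_scheme("invivo", seed=0)


@pytest.fixture(scope="session")
def exvivo_scheme():
    return make_scheme("exvivo", seed=0)


def make_mixture_signal(
    scheme,
    fiber_fraction,
    lambda_par,
    lambda_perp,
    restricted,
    nonrestricted,
    restricted_D=0.3,
    nonrestricted_D=1.8,
    orientation=(0.0, 0.0, 1.0),
    s0=1.0,
    limits=(0.0, 3.0),
):
    """Noise-free two-delta mixture voxel signal."""
    fiber = FiberComponent(fiber_fraction, lambda_par, lambda_perp, np.asarray(orientation))
    spectrum = IsotropicSpectrum(
        np.array([restricted_D, nonrestricted_D]),
        np.array([restricted, nonrestricted]),
        limits,
    )
    return forward_signal(VoxelModel(fiber, spectrum, s0), scheme)


def renormalized(fiber, restricted, nonrestricted):
    """Scale a printed fraction triplet to sum to 1."""
    total = fiber + restricted + nonrestricted
    return fiber / total, restricted / total, nonrestricted / total


@pytest.fixture(scope="session")
def day30_compositions():
    """Renormalised day-30 group compositions used across tests:
    (fiber, restricted, nonrestricted, lambda_par, lambda_perp)."""
    sham = (*renormalized(0.81, 0.05, 0.06), 1.84, 0.14)
    tbi = (*renormalized(0.61, 0.18, 0.10), 1.61, 0.23)
    return {"sham": sham, "TBI": tbi}


def random_rotation(rng):
    """Haar-uniform rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
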