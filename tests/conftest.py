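import numpy as np
import pytest

from shoremaps.phantom import (
    CohortSpec,
    CompartmentSpec,
    WM_EIGENVALUES,
    build_toy_geometry,
    simulate_measure_table,
    simulate_voxel_signal,
)
from shoremaps.qspace import build_dsi_scheme, subset_by_bvalue
from shoremaps.shore import estimate_zeta, fit_shore
from shoremaps.sphere import icosphere_sampling

TAU = 0.0538


@pytest.fixture(scope="session")
def scheme():
    return build_dsi_scheme(5, 8000.0, TAU)


@pytest.fixture(scope="session")
def dti_scheme(scheme):
    return subset_by_bvalue(scheme, 0.0, 1500.0)


@pytest.fixture(scope="session")
def sphere642():
    return icosphere_sampling(3)


@pytest.fixture(scope="session")
def geometry():
    return build_toy_geometry()


@pytest.fixture(scope="session")
def cohort(geometry):
    """Default 10+10 measure-level cohort with its covariates."""
    spec = CohortSpec(seed=2024)
    return simulate_measure_table(spec, geometry)


def tensor_signal(scheme, evals, orientation=(0.0, 0.0, 1.0)):
    comp = CompartmentSpec(tuple(evals), tuple(orientation), 1.0)
    return simulate_voxel_signal([comp], scheme)


def shore_fit_of_tensor(scheme, evals, orientation=(0.0, 0.0, 1.0), n_max=8):
    """Fit the SHORE basis to a noiseless single-tensor signal with the
    MD-matched scale."""
    sig = tensor_signal(scheme, evals, orientation)
    md_true = float(np.mean(evals))
    zeta = estimate_zeta(md_true, scheme.tau)
    return fit_shore(sig, scheme, n_max=n_max, zeta=zeta)


@pytest.fixture(scope="session")
def wm_fit(scheme):
    return shore_fit_of_tensor(scheme, WM_EIGENVALUES)
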