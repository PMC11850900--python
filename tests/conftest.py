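import numpy as np
import pytest

from fodfsr import csd, phantom, sh


@pytest.fixture(scope="session")
def scheme():
    return phantom.make_scheme(seed=42)


@pytest.fixture(scope="session")
def response():
    return phantom.ResponseFunction()


@pytest.fixture(scope="session")
def quad():
    """Exact quadrature grid for band-limited spherical integrals."""
    return sh.sphere_quadrature()


@pytest.fixture(scope="session")
def quad_design(quad):
    return sh.build_basis(quad, sh.SHBasisSpec(8))


@pytest.fixture(scope="session")
def peak_tess():
    return sh.default_tessellation(4, hemisphere=True)


@pytest.fixture(scope="session")
def peak_design(peak_tess):
    return sh.build_basis(peak_tess, sh.SHBasisSpec(8))


def single_voxel_config(dirs, fracs):
    """FiberConfig with one voxel holding the given fibers."""
    ori = np.zeros((1, 1, 1, 5, 3))
    frac = np.zeros((1, 1, 1, 5))
    for k, (d, f) in enumerate(zip(dirs, fracs)):
        d = np.asarray(d, dtype=float)
        ori[0, 0, 0, k] = d / np.linalg.norm(d)
        frac[0, 0, 0, k] = f
    return phantom.FiberConfig(ori, frac)


def voxel_signal(dirs, fracs, scheme, response):
    """Noiseless single-shell signal of one multi-fiber voxel."""
    cfg = single_voxel_config(dirs, fracs)
    return phantom.simulate_signal(cfg, response, scheme).signal[0, 0, 0]
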