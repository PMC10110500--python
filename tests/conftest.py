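import numpy as np
import pytest

import gliaquant as gq


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def acq_params():
    """The reference acquisition: NA 1.3 array detector, GFP-class dyes."""
    return gq.AcquisitionParams(na=1.3, lambda_ex=488, lambda_em=520, ri=1.338)


@pytest.fixture(scope="session")
def small_psf():
    """Modest 3x5x5 blur kernel at the phantom's 0.5 µm voxel scale."""
    import warnings

    params = gq.AcquisitionParams(na=1.1, lambda_ex=488, lambda_em=520, ri=1.338)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return gq.theoretical_psf(params, (0.5, 0.5, 0.5), shape=(3, 5, 5))


@pytest.fixture(scope="session")
def mg_phantom():
    """One 5-cell phantom shared across read-only tests."""
    grid, truth, gt = gq.make_mg_phantom(seed=1, n_cells=5)
    return grid, truth, gt
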