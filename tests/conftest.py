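import numpy as np
import pytest

import densitytail as dt


@pytest.fixture(scope="session")
def std_gauss_3d():
    """Standard 3-D Gaussian model plus 1e5 seeded samples."""
    return dt.fixtures.standard_gaussian_fixture(3, 100_000, seed=101)


@pytest.fixture(scope="session")
def bivariate_mixture():
    """The 8-component bimodal bivariate fixture with its 1e5 samples."""
    return dt.fixtures.bivariate_mixture_fixture(seed=202)


@pytest.fixture(scope="session")
def vitalsign():
    """400-kernel vital-sign model plus a labelled two-regime stream."""
    model, frame = dt.fixtures.vitalsign_fixture(4000, 400, seed=7)
    return model, frame


def gpd_depth_sample(shape, scale, count, seed, u=None):
    """Image-space values whose shortfall depths under u are exact GPD draws.

    Returns (values, u): with u at the GPD support endpoint the values fill
    [0, u]; for unbounded shapes u is placed just above the sample maximum.
    """
    params = dt.GPDParams(shape, scale)
    e = dt.fixtures.gpd_fixture(params, None, count, seed=seed)
    if u is None:
        u = params.endpoint if np.isfinite(params.endpoint) else float(e.max()) * 1.000001
    return u - e, float(u)
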