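import numpy as np
import pytest

from lvmcm.environment import EnvironmentField, covariance
from lvmcm.landscape import build_landscape


@pytest.fixture(scope="session")
def landscape8():
    return build_landscape(8, seed=5)


@pytest.fixture(scope="session")
def env8(landscape8):
    return EnvironmentField(Sigma=covariance(landscape8.dist, 10.0))


@pytest.fixture(scope="session")
def collinear3():
    """Three collinear patches at x = 0, 1, 2 with chain adjacency."""
    import scipy.sparse as sp
    from scipy.spatial import distance_matrix

    from lvmcm.landscape import Landscape, build_dispersal

    coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
    dist = distance_matrix(coords, coords)
    adjacency = np.array(
        [[False, True, False], [True, False, True], [False, True, False]]
    )
    D = build_dispersal(dist, adjacency, e=0.01, ell=0.5)
    return Landscape(N=3, coords=coords, dist=dist, adjacency=adjacency, D=D,
                     e=0.01, ell=0.5)
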