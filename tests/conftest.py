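import warnings

import numpy as np
import pytest

from cardiofuse import ionic_models as im
from cardiofuse import simulator as sm
from cardiofuse import tissue as ts


@pytest.fixture(autouse=True)
def _quiet_numpy():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def cm_rest():
    return im.settle_to_rest("CM")


@pytest.fixture(scope="session")
def cf_rest():
    return im.settle_to_rest("CF")


@pytest.fixture(scope="session")
def tiny_mixed():
    """3x3x6 lattice with a 2-layer CF block: the oracle-scale system."""
    geo = ts.build_elongated_tissue(3, 3, 6, (2, 3),
                                    ts.BoundaryProfile(sigma=0.0, seed=0))
    coup = ts.build_coupling_map(geo)
    return geo, coup


@pytest.fixture(scope="session")
def test_lattice_dims():
    """Scaled lattice for conduction experiments: reduced cross-section,
    full axial extent (the propagation axis is what matters)."""
    return (6, 6, 100)
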