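import logging
import warnings

import numpy as np
import pytest

from mesocortex import field_dynamics as fd
from mesocortex import map_geometry as mg


@pytest.fixture(autouse=True)
def _quiet_logs():
    logging.disable(logging.WARNING)
    yield
    logging.disable(logging.NOTSET)


@pytest.fixture
def default_map():
    """A standard local-map spec: center at the origin, 90-degree rotation."""
    return mg.LocalMapSpec(p0=0j, p_prime=0.5j, n=2, chirality=1, nu=1.0)


@pytest.fixture
def frame():
    return mg.hex_patch_lattice(0.8, (0.0, 8.0, 0.0, 8.0))


@pytest.fixture
def suppress_instability():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", fd.UnstableFieldWarning)
        yield


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
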