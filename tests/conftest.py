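import math

import numpy as np
import pytest

from blastula.laws import LOGNORMAL, NORMAL, Law
from blastula.model import GroupModel


@pytest.fixture(scope="session")
def default_model() -> GroupModel:
    return GroupModel.default()


@pytest.fixture(scope="session")
def small_model() -> GroupModel:
    """Generations 6-8 only: 224 cells, fast."""
    return GroupModel.default(max_generation=8)


def make_zero_noise_model(max_generation: int = 10) -> GroupModel:
    """All sigmas zero, parameters on the 2-min acquisition grid.

    Every draw is deterministic and every division time is a multiple of the
    grid step, so feature extraction recovers the configured values exactly.
    """
    m = GroupModel.default(max_generation=max_generation)
    mus = {7: 44.0, 8: 56.0, 9: 70.0, 10: 90.0}
    for (n, k) in list(m.cycle):
        mu = mus.get(n, 60.0)
        m.cycle[(n, k)] = Law(NORMAL, mu, 0.0)
        m.vol_ratio[(n, k)] = Law(LOGNORMAL, math.log(0.5), 0.0)
        m.surf_ratio[(n, k)] = Law(LOGNORMAL, (2 / 3) * math.log(0.5), 0.0)
    for k in m.types:
        m.init_m[k] = Law(NORMAL, 44.0, 0.0)
        m.init_vol[k] = Law(LOGNORMAL, math.log(2048.0), 0.0)
        m.init_surf[k] = Law(LOGNORMAL, math.log(1024.0), 0.0)
    return m


@pytest.fixture(scope="session")
def zero_noise_model() -> GroupModel:
    return make_zero_noise_model()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
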