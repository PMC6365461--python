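import datetime as dt

import numpy as np
import pytest

from canopylux import FisheyeGeometry, RadiationConfig
from canopylux.synthetic import default_geometry

#: study site (Oakville, CA) in local standard time
OAKVILLE = dict(latitude=38.428, longitude=-122.409, utc_offset=-8.0)
RIPENING_START = dt.date(2017, 7, 24)
HARVEST = dt.date(2017, 9, 9)


@pytest.fixture
def oak_config() -> RadiationConfig:
    return RadiationConfig(**OAKVILLE)


@pytest.fixture
def geometry() -> FisheyeGeometry:
    return default_geometry(201)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170909)
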