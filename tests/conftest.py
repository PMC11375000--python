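import datetime as dt

import numpy as np
import pytest

from icebloom.config import ScenarioConfig
from icebloom.light_profiles import IrradianceProfile

UTC = dt.timezone.utc
STAMP = dt.datetime(2020, 3, 28, 12, 0, tzinfo=UTC)
SENSOR_DEPTHS = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 9.0, 14.0, 21.0, 32.0, 50.0)


def make_profile(e0=5.0, kappa=0.05, s=0.0, ell=3.0, depths=SENSOR_DEPTHS,
                 noise=None, site="hh", stamp=STAMP):
    """Exponential profile with optional shading deficit and noise factors."""
    z = np.asarray(depths, dtype=float)
    par = e0 * np.exp(-kappa * z) * (1.0 - s * np.exp(-z / ell))
    if noise is not None:
        par = par * np.asarray(noise, dtype=float)
    return IrradianceProfile(site=site, timestamp=stamp, depths=tuple(z),
                             par=tuple(float(v) for v in par))


@pytest.fixture
def sixty_day_scenario():
    """Default-condition scenario trimmed to a 60-day window around onset."""
    return ScenarioConfig(seed=1, start=dt.date(2020, 2, 26),
                          end=dt.date(2020, 4, 25))
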