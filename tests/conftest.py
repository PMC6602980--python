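import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    # the series_factory fixture is a stateless constructor, safe under @given
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")

from poincare_hrv import HeartRateSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20180)


def make_series(values, start=0.0, dt=1.0, mask=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(len(values), dtype=bool)
    return HeartRateSeries(
        start_time=start, sampling_interval=dt, values=values,
        valid_mask=np.asarray(mask, dtype=bool),
    )


@pytest.fixture
def series_factory():
    return make_series
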