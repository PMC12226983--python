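import numpy as np
import pytest

from tidkde import AthleteProfile, HRSeries
from tidkde.preprocessing import RelativeIntensitySeries
from tidkde.zones_tiz import DEFAULT_ZONE_MODEL


@pytest.fixture
def model():
    return DEFAULT_ZONE_MODEL


@pytest.fixture
def profile():
    return AthleteProfile(athlete_id="A01", hr_max=200.0)


def make_series(hr, t=None, session_id="S1", athlete_id="A01"):
    hr = np.asarray(hr, dtype=float)
    if t is None:
        t = np.arange(hr.size)
    return HRSeries(session_id=session_id, athlete_id=athlete_id, t=t, hr=hr)


def make_rel(values, session_id="S1", athlete_id="A01"):
    return RelativeIntensitySeries(
        session_id=session_id,
        athlete_id=athlete_id,
        values=np.asarray(values, dtype=np.int64),
    )


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def rel_factory():
    return make_rel
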