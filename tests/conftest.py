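from __future__ import annotations

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pmremote.protocol import ParticleRecord, RecordSeries

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")

T0 = datetime(2017, 7, 1, 0, 0, tzinfo=timezone.utc)
MINUTE = timedelta(minutes=1)


@pytest.fixture
def t0() -> datetime:
    return T0


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170701)


@pytest.fixture
def make_series():
    """Build a minute series from (minute_index, small, large) triples."""

    def build(triples, device_id="DEV-A", start=T0) -> RecordSeries:
        return RecordSeries(
            device_id,
            [
                ParticleRecord(device_id, start + m * MINUTE, s, l)
                for m, s, l in triples
            ],
        )

    return build


@pytest.fixture
def flat_series(make_series):
    """100 consecutive minutes of constant counts."""
    return make_series([(m, 1500, 100) for m in range(100)])
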