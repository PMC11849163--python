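import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from orair.ingest import RECORD_SECONDS, SIZE_BINS, ParticleRecord, SamplingPeriod

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


def make_records(columns, start=dt.time(8, 0, 0)):
    """Build ParticleRecords from per-bin count lists (one list per size bin)."""
    n = len(columns[0])
    assert all(len(c) == n for c in columns)
    t0 = start.hour * 3600 + start.minute * 60 + start.second
    out = []
    for i in range(n):
        sec = t0 + i * RECORD_SECONDS
        t = dt.time(sec // 3600, (sec % 3600) // 60, sec % 60)
        out.append(ParticleRecord(t, {b: int(col[i]) for b, col in zip(SIZE_BINS, columns)}))
    return out


def make_period(columns, surgery_id="S01", period_index=1, partial=None):
    """A SamplingPeriod from per-bin count lists; partial inferred from length."""
    records = make_records(columns)
    if partial is None:
        partial = len(records) != 120
    return SamplingPeriod(surgery_id, period_index, tuple(records), partial=partial)


@pytest.fixture(scope="session")
def table1():
    from orair.ingest import load_table1_periods

    diathermy, clean = load_table1_periods()
    return {"diathermy": diathermy, "clean": clean}
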