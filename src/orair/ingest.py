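"""Reading, validating and writing particle-counter and CFU air-sample tables.

The real-time bioaerosol counter draws 5 dm³ of air per minute and reports,
every 5 seconds, the number of fluorescing particles in six optical size bins
(0.5–<1, 1–<2, 2–<3, 3–<5, 5–<10 and ≥10 µm).  120 consecutive 5-second
records form one 10-minute sampling period, i.e. 50 dm³ of sampled air.  The
culture-based reference method draws 1 m³ through a gelatine filter over the
same 10 minutes and reports aerobic colony-forming units per m³ (CFU/m³).

This module holds the core domain types (:class:`SizeBin`,
:class:`ParticleRecord`, :class:`SamplingPeriod`, :class:`CfuSample`) and the
CSV dialects used throughout the pipeline.
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "RECORD_SECONDS",
    "RECORDS_PER_PERIOD",
    "PERIOD_SECONDS",
    "FLOW_DM3_PER_MIN",
    "sampled_volume_dm3",
    "SizeBin",
    "SIZE_BINS",
    "GE3_BINS",
    "ParticleRecord",
    "SamplingPeriod",
    "CfuSample",
    "IngestError",
    "IncompletePeriodError",
    "read_particle_series",
    "read_particle_sessions",
    "write_particle_series",
    "write_particle_sessions",
    "read_cfu_samples",
    "write_cfu_samples",
    "read_schedule",
    "write_schedule",
    "segment_periods",
    "segment_sessions",
    "load_table1_periods",
]

#: duration of one counting draw, seconds
RECORD_SECONDS = 5
#: number of 5-second draws in one sampling period
RECORDS_PER_PERIOD = 120
#: duration of one sampling period, seconds (10 minutes)
PERIOD_SECONDS = RECORD_SECONDS * RECORDS_PER_PERIOD
#: instrument sampling flow, dm³ of air per minute
FLOW_DM3_PER_MIN = 5.0


def sampled_volume_dm3(n_records: int) -> float:
    """Air volume (dm³) drawn during ``n_records`` consecutive 5-s draws.

    A complete 120-record period at 5 dm³/min therefore samples 50 dm³,
    which is why period totals are expressed per 50 dm³.
    """
    return FLOW_DM3_PER_MIN * n_records * RECORD_SECONDS / 60.0


class IngestError(ValueError):
    """Raised for malformed or inconsistent input tables."""


class IncompletePeriodError(IngestError):
    """Raised when a scheduled 10-minute window does not hold 120 records."""


class SizeBin(Enum):
    """Optical particle-size channels of the counter.

    Six half-open bins ``[lo, hi)`` in µm, the last open-ended.  Enum values
    double as the CSV column names.
    """

    B05_1 = "b05_1"
    B1_2 = "b1_2"
    B2_3 = "b2_3"
    B3_5 = "b3_5"
    B5_10 = "b5_10"
    B10P = "b10p"

    @property
    def edges(self) -> tuple[float, float]:
        """Lower and upper bin edge in µm (upper edge ``inf`` for ≥10 µm)."""
        return _EDGES[self]


_EDGES: dict[SizeBin, tuple[float, float]] = {
    SizeBin.B05_1: (0.5, 1.0),
    SizeBin.B1_2: (1.0, 2.0),
    SizeBin.B2_3: (2.0, 3.0),
    SizeBin.B3_5: (3.0, 5.0),
    SizeBin.B5_10: (5.0, 10.0),
    SizeBin.B10P: (10.0, math.inf),
}

#: all six bins, ordered by lower edge
SIZE_BINS: tuple[SizeBin, ...] = tuple(SizeBin)
#: the three bins at or above 3 µm — the size range retained by the gelatine
#: filter of the culture sampler, hence the comparison size class
GE3_BINS: tuple[SizeBin, ...] = (SizeBin.B3_5, SizeBin.B5_10, SizeBin.B10P)


def _time_seconds(t: dt.time) -> int:
    return t.hour * 3600 + t.minute * 60 + t.second


def _seconds_time(s: int) -> dt.time:
    if not 0 <= s < 86400:
        raise IngestError(f"time-of-day out of range (no midnight wrap): {s} s")
    return dt.time(s // 3600, (s % 3600) // 60, s % 60)


@dataclass(frozen=True)
class ParticleRecord:
    """One 5-second observation: time of day plus a count per size bin."""

    timestamp: dt.time
    counts: Mapping[SizeBin, int]

    def __post_init__(self) -> None:
        if set(self.counts) != set(SIZE_BINS):
            raise IngestError("counts must cover exactly the six size bins")
        for b, c in self.counts.items():
            if not isinstance(c, (int,)) or isinstance(c, bool) or c < 0:
                raise IngestError(f"count for {b.value} must be a non-negative integer, got {c!r}")

    @property
    def seconds(self) -> int:
        """Seconds since midnight."""
        return _time_seconds(self.timestamp)


@dataclass
class SamplingPeriod:
    """One 10-minute window of 120 consecutive 5-second records.

    ``partial=True`` marks an excerpt (e.g. a printed table fragment) and
    relaxes the 120-record requirement; downstream operations only accept
    partial periods in an explicit excerpt mode.
    """

    surgery_id: str
    period_index: int
    records: tuple[ParticleRecord, ...]
    partial: bool = False
    distorted: bool | None = None

    def __post_init__(self) -> None:
        self.records = tuple(self.records)
        if not self.partial and len(self.records) != RECORDS_PER_PERIOD:
            raise IncompletePeriodError(
                f"{self.surgery_id} period {self.period_index}: "
                f"{len(self.records)} records, expected {RECORDS_PER_PERIOD}"
            )
        secs = [r.seconds for r in self.records]
        for a, b in zip(secs, secs[1:]):
            if b - a != RECORD_SECONDS:
                raise IngestError(
                    f"{self.surgery_id} period {self.period_index}: records not "
                    f"strictly increasing with {RECORD_SECONDS}-s spacing "
                    f"({_seconds_time(a)} -> {_seconds_time(b)})"
                )

    def bin_counts(self, size_bin: SizeBin) -> list[int]:
        """The per-record count series for one size bin."""
        return [r.counts[size_bin] for r in self.records]


@dataclass(frozen=True)
class CfuSample:
    """One 10-minute culture result: aerobic CFU per m³ of air.

    Discarded plates (contaminated during sampling, or condensation under the
    lid) carry no usable count; ``cfu_per_m3`` is then ``None``.
    """

    surgery_id: str
    period_index: int
    cfu_per_m3: int | None
    discarded: bool = False

    def __post_init__(self) -> None:
        if not self.discarded:
            if self.cfu_per_m3 is None:
                raise IngestError(
                    f"{self.surgery_id} period {self.period_index}: missing CFU "
                    "count on a non-discarded sample"
                )
            if self.cfu_per_m3 < 0:
                raise IngestError("cfu_per_m3 must be non-negative")


# ---------------------------------------------------------------------------
# particle-series CSV dialect

#: default column map: timestamp column plus one column per size bin,
#: ordered 0.5–<1 µm first as on the instrument display
DEFAULT_DIALECT: dict[str, str] = {"timestamp": "timestamp"} | {
    b.value: b.value for b in SIZE_BINS
}
#: name of the optional per-surgery key column in multi-surgery files
SURGERY_COLUMN = "surgery_id"


def _parse_timestamp(raw: str, row: int) -> dt.time:
    try:
        return dt.datetime.strptime(raw.strip(), "%H:%M:%S").time()
    except ValueError:
        raise IngestError(f"row {row}: malformed timestamp {raw!r} (expected hh:mm:ss)") from None


def _parse_count(raw: str, col: str, row: int) -> int:
    s = raw.strip()
    if not s.isdigit():
        raise IngestError(f"row {row}, column {col}: count must be a non-negative integer, got {raw!r}")
    return int(s)


def _read_particle_frame(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def _parse_particle_rows(df: pd.DataFrame, dialect: Mapping[str, str]) -> list[ParticleRecord]:
    ts_col = dialect["timestamp"]
    bin_cols = {b: dialect[b.value] for b in SIZE_BINS}
    missing = [c for c in [ts_col, *bin_cols.values()] if c not in df.columns]
    if missing:
        raise IngestError(f"missing columns: {missing}")
    records: list[ParticleRecord] = []
    seen: set[int] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        row_d = dict(zip(df.columns, row))
        t = _parse_timestamp(row_d[ts_col], idx)
        sec = _time_seconds(t)
        if sec in seen:
            raise IngestError(f"row {idx}: duplicate timestamp {row_d[ts_col]!r}")
        seen.add(sec)
        counts = {b: _parse_count(row_d[col], col, idx) for b, col in bin_cols.items()}
        records.append(ParticleRecord(t, counts))
    records.sort(key=lambda r: r.seconds)
    return records


def read_particle_series(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[ParticleRecord]:
    """Read a single-surgery particle time series from CSV.

    ``dialect`` maps the logical fields (``timestamp`` plus the six bin
    labels) to CSV column names; the default expects
    ``timestamp,b05_1,b1_2,b2_3,b3_5,b5_10,b10p``.  Records are returned
    sorted by time of day; duplicate timestamps, malformed times and
    non-integer or negative counts raise :class:`IngestError` naming the row.
    """
    return _parse_particle_rows(_read_particle_frame(path), dialect or DEFAULT_DIALECT)


def read_particle_sessions(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> dict[str, list[ParticleRecord]]:
    """Read a multi-surgery particle CSV keyed by a ``surgery_id`` column."""
    df = _read_particle_frame(path)
    if SURGERY_COLUMN not in df.columns:
        raise IngestError(f"missing column: {SURGERY_COLUMN}")
    out: dict[str, list[ParticleRecord]] = {}
    for sid, sub in df.groupby(SURGERY_COLUMN, sort=False):
        out[str(sid)] = _parse_particle_rows(
            sub.drop(columns=[SURGERY_COLUMN]).reset_index(drop=True),
            dialect or DEFAULT_DIALECT,
        )
    return out


def _record_row(r: ParticleRecord) -> list[str]:
    return [r.timestamp.strftime("%H:%M:%S")] + [str(r.counts[b]) for b in SIZE_BINS]


def write_particle_series(path: str | Path, records: Iterable[ParticleRecord]) -> None:
    """Write records in the default CSV dialect."""
    header = ["timestamp"] + [b.value for b in SIZE_BINS]
    lines = [",".join(header)] + [",".join(_record_row(r)) for r in records]
    Path(path).write_text("\n".join(lines) + "\n")


def write_particle_sessions(
    path: str | Path, sessions: Mapping[str, Sequence[ParticleRecord]]
) -> None:
    """Write a multi-surgery particle CSV with a leading ``surgery_id`` column."""
    header = [SURGERY_COLUMN, "timestamp"] + [b.value for b in SIZE_BINS]
    lines = [",".join(header)]
    for sid, records in sessions.items():
        lines += [",".join([sid] + _record_row(r)) for r in records]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# CFU table

def read_cfu_samples(path: str | Path, max_period: int = 6) -> list[CfuSample]:
    """Read the CFU sample table (``surgery_id,period_index,cfu_per_m3,discarded``).

    Discarded rows are retained with the flag set and may have an empty count.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["surgery_id", "period_index", "cfu_per_m3", "discarded"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IngestError(f"missing columns: {missing}")
    out: list[CfuSample] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        row_d = dict(zip(df.columns, row))
        try:
            pidx = int(row_d["period_index"])
        except ValueError:
            raise IngestError(f"row {idx}: bad period_index {row_d['period_index']!r}") from None
        if not 1 <= pidx <= max_period:
            raise IngestError(f"row {idx}: period_index {pidx} outside 1–{max_period}")
        raw_disc = row_d["discarded"].strip().lower()
        if raw_disc in {"true", "1", "yes"}:
            discarded = True
        elif raw_disc in {"false", "0", "no"}:
            discarded = False
        else:
            raise IngestError(f"row {idx}: bad discarded flag {row_d['discarded']!r}")
        raw_cfu = row_d["cfu_per_m3"].strip()
        if raw_cfu == "":
            cfu: int | None = None
            if not discarded:
                raise IngestError(f"row {idx}: missing cfu_per_m3 on non-discarded sample")
        else:
            cfu = _parse_count(raw_cfu, "cfu_per_m3", idx)
        out.append(CfuSample(str(row_d["surgery_id"]), pidx, cfu, discarded))
    return out


def write_cfu_samples(path: str | Path, samples: Iterable[CfuSample]) -> None:
    lines = ["surgery_id,period_index,cfu_per_m3,discarded"]
    for s in samples:
        cfu = "" if s.cfu_per_m3 is None else str(s.cfu_per_m3)
        lines.append(f"{s.surgery_id},{s.period_index},{cfu},{'true' if s.discarded else 'false'}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# schedules and segmentation

def read_schedule(path: str | Path) -> dict[str, list[dt.time]]:
    """Read period start times (``surgery_id,period_index,start_time``).

    Returns, per surgery, the list of start times ordered by period index.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["surgery_id", "period_index", "start_time"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IngestError(f"missing columns: {missing}")
    tmp: dict[str, dict[int, dt.time]] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        row_d = dict(zip(df.columns, row))
        sid = str(row_d["surgery_id"])
        pidx = int(row_d["period_index"])
        tmp.setdefault(sid, {})[pidx] = _parse_timestamp(row_d["start_time"], idx)
    out: dict[str, list[dt.time]] = {}
    for sid, by_idx in tmp.items():
        if sorted(by_idx) != list(range(1, len(by_idx) + 1)):
            raise IngestError(f"{sid}: period indices not contiguous from 1")
        out[sid] = [by_idx[i] for i in range(1, len(by_idx) + 1)]
    return out


def write_schedule(path: str | Path, schedule: Mapping[str, Sequence[dt.time]]) -> None:
    lines = ["surgery_id,period_index,start_time"]
    for sid, starts in schedule.items():
        for i, t in enumerate(starts, start=1):
            lines.append(f"{sid},{i},{t.strftime('%H:%M:%S')}")
    Path(path).write_text("\n".join(lines) + "\n")


def segment_periods(
    records: Sequence[ParticleRecord],
    starts: Sequence[dt.time],
    surgery_id: str = "",
    *,
    policy: str = "reject",
) -> list[SamplingPeriod]:
    """Cut a record stream into scheduled 10-minute sampling periods.

    Each start time opens a half-open window ``[start, start+600 s)``;
    records in the 2–3-minute filter-change breaks between windows belong to
    no period.  A window holding fewer or more than 120 records raises
    :class:`IncompletePeriodError` under the default ``policy="reject"``;
    ``policy="drop"`` skips it with a warning instead.
    """
    if policy not in {"reject", "drop"}:
        raise ValueError(f"unknown policy {policy!r}")
    start_secs = [_time_seconds(t) for t in starts]
    for a, b in zip(start_secs, start_secs[1:]):
        if b < a + PERIOD_SECONDS:
            raise IngestError(f"{surgery_id}: overlapping period windows in schedule")
    periods: list[SamplingPeriod] = []
    for i, s0 in enumerate(start_secs, start=1):
        window = [r for r in records if s0 <= r.seconds < s0 + PERIOD_SECONDS]
        if len(window) != RECORDS_PER_PERIOD:
            msg = (
                f"{surgery_id} period {i}: window at {_seconds_time(s0)} holds "
                f"{len(window)} records, expected {RECORDS_PER_PERIOD}"
            )
            if policy == "reject":
                raise IncompletePeriodError(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        periods.append(SamplingPeriod(surgery_id, i, tuple(window)))
    return periods


def segment_sessions(
    sessions: Mapping[str, Sequence[ParticleRecord]],
    schedule: Mapping[str, Sequence[dt.time]],
    *,
    policy: str = "reject",
) -> list[SamplingPeriod]:
    """Segment every surgery's record stream against its schedule."""
    missing = sorted(set(sessions) - set(schedule))
    if missing:
        raise IngestError(f"no schedule for surgeries: {missing}")
    out: list[SamplingPeriod] = []
    for sid, records in sessions.items():
        out.extend(segment_periods(records, schedule[sid], sid, policy=policy))
    return out


# ---------------------------------------------------------------------------
# packaged worked-example fixtures

def load_table1_periods() -> tuple[SamplingPeriod, SamplingPeriod]:
    """Load the two packaged 16-record excerpts (diathermy, clean).

    Both are printed instrument-output fragments, far shorter than a full
    period, and are therefore returned as ``partial`` periods for use in the
    excerpt modes of the distortion and aggregation operations.
    """
    from importlib.resources import files

    data = files("orair.data")
    out = []
    for name, sid in [("table1_diathermy.csv", "T1-diathermy"), ("table1_clean.csv", "T1-clean")]:
        with (data / name).open() as fh:
            df = pd.read_csv(fh, dtype=str, keep_default_na=False)
        records = _parse_particle_rows(df, DEFAULT_DIALECT)
        out.append(SamplingPeriod(sid, 1, tuple(records), partial=True))
    return out[0], out[1]
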