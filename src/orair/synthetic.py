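"""Synthetic operating-room air-sampling sessions with full ground truth.

The generator emulates the statistical structure the analysis assumes rather
than aerosol physics.  Each surgery contributes six 10-minute periods.  A
latent bioparticle-release intensity λ — expected FBP ≥3 µm per 50 dm³ — is
constant within a period and varies between periods through a Poisson number
of multiplicative activity events (staff movement, door openings and the
like, not modelled individually):

    λ = base_intensity × (1 + activity_amplitude × E),   E ~ Poisson(event_rate · 1/6 h)

Given λ, the two instruments are conditionally independent: the 5-second
counts in each size bin are Poisson with mean λ·f_bin/f_≥3µm/120 (f being
the bin allocation fractions), and the period's CFU/m³ is Poisson with mean
cfu_coupling·λ.  The shared λ is what induces the positive FBP–CFU
dependence the analysis measures.

Diathermy bursts and plate discards are injected on explicit schedules (or,
for discards, an optional Bernoulli rate) so the ground truth is exact for
detector-sensitivity and exclusion-bookkeeping tests.  Burst counts are
added on top of the baseline draws, so injection never reduces a count.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ingest import (
    PERIOD_SECONDS,
    RECORD_SECONDS,
    RECORDS_PER_PERIOD,
    SIZE_BINS,
    CfuSample,
    ParticleRecord,
    SizeBin,
    write_cfu_samples,
    write_particle_sessions,
    write_schedule,
)

__all__ = [
    "DEFAULT_BIN_FRACTIONS",
    "DEFAULT_BURST_MEANS",
    "BurstSpec",
    "SessionConfig",
    "GroundTruth",
    "SimulatedSession",
    "SyntheticError",
    "surgery_ids",
    "simulate_session",
    "inject_bursts",
    "study_conditions",
]


class SyntheticError(ValueError):
    """Raised for invalid generator configurations or schedules."""


#: allocation of emitted particles across size bins.  Most mass sits below
#: 3 µm, consistent with undisturbed instrument output where ≥3 µm counts
#: are sparse; the ≥3 µm share is 0.25.
DEFAULT_BIN_FRACTIONS: dict[SizeBin, float] = {
    SizeBin.B05_1: 0.40,
    SizeBin.B1_2: 0.22,
    SizeBin.B2_3: 0.13,
    SizeBin.B3_5: 0.13,
    SizeBin.B5_10: 0.08,
    SizeBin.B10P: 0.04,
}

#: mean added counts per 5-second record during a diathermy burst, per bin —
#: magnitudes on the scale of the printed diathermy excerpt (smallest bin
#: around 80 per draw, decaying steeply with size)
DEFAULT_BURST_MEANS: dict[SizeBin, float] = {
    SizeBin.B05_1: 80.0,
    SizeBin.B1_2: 33.0,
    SizeBin.B2_3: 11.0,
    SizeBin.B3_5: 3.0,
    SizeBin.B5_10: 1.0,
    SizeBin.B10P: 0.1,
}

#: filter-change break between consecutive periods, seconds (2.5 min)
BREAK_SECONDS = 150
#: session start time of day for every generated surgery
SESSION_START = dt.time(8, 0, 0)


def surgery_ids(n: int) -> list[str]:
    """Surgery identifiers S01..Snn."""
    return [f"S{i:02d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class BurstSpec:
    """One scheduled diathermy burst: where it starts and how long it lasts."""

    surgery_id: str
    period_index: int
    start_record: int
    n_records: int


@dataclass(frozen=True)
class SessionConfig:
    """Generator settings; defaults emulate a quiet turbulent-airflow OR.

    All intensity parameters are plausibility choices on the scale of the
    instruments' reported axes (FBP ≥3 µm per 50 dm³ up to ~100, CFU/m³ up
    to ~25), not estimates from data.

    ``discard_schedule=None`` draws plate discards Bernoulli(
    ``discard_probability``) per period; an explicit schedule (set of
    (surgery_id, period_index)) overrides the draw.
    """

    n_surgeries: int = 18
    periods_per_surgery: int = 6
    #: expected FBP ≥3 µm per 50 dm³ with no activity events
    base_intensity: float = 12.0
    #: multiplicative effect of one activity event on λ
    activity_amplitude: float = 1.0
    #: activity events per hour
    event_rate: float = 6.0
    #: expected CFU/m³ per unit of latent ≥3 µm intensity
    cfu_coupling: float = 0.3
    bin_fractions: Mapping[SizeBin, float] = field(
        default_factory=lambda: dict(DEFAULT_BIN_FRACTIONS)
    )
    burst_schedule: tuple[BurstSpec, ...] = ()
    burst_params: Mapping[SizeBin, float] = field(
        default_factory=lambda: dict(DEFAULT_BURST_MEANS)
    )
    #: marginal plate-discard probability (≈ 8 discards per 108 periods)
    discard_probability: float = 8.0 / 108.0
    discard_schedule: frozenset[tuple[str, int]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_surgeries < 1 or self.periods_per_surgery < 1:
            raise SyntheticError("n_surgeries and periods_per_surgery must be >= 1")
        if set(self.bin_fractions) != set(SIZE_BINS):
            raise SyntheticError("bin_fractions must cover exactly the six size bins")
        total = sum(self.bin_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise SyntheticError(f"bin_fractions must sum to 1, got {total}")
        if any(f < 0 for f in self.bin_fractions.values()):
            raise SyntheticError("bin_fractions must be non-negative")
        for name in ("base_intensity", "activity_amplitude", "event_rate", "cfu_coupling"):
            if getattr(self, name) < 0:
                raise SyntheticError(f"{name} must be non-negative")
        if not 0.0 <= self.discard_probability <= 1.0:
            raise SyntheticError("discard_probability must be in [0, 1]")
        ids = set(surgery_ids(self.n_surgeries))
        for b in self.burst_schedule:
            if b.surgery_id not in ids:
                raise SyntheticError(f"burst for unknown surgery {b.surgery_id}")
            if not 1 <= b.period_index <= self.periods_per_surgery:
                raise SyntheticError(f"burst period_index {b.period_index} out of range")
            if b.start_record < 0 or b.start_record + b.n_records > RECORDS_PER_PERIOD:
                raise SyntheticError(f"burst exceeds the 120-record period: {b}")

    @property
    def frac_ge3(self) -> float:
        from .ingest import GE3_BINS

        return sum(self.bin_fractions[b] for b in GE3_BINS)

    @property
    def n_periods(self) -> int:
        return self.n_surgeries * self.periods_per_surgery

    @property
    def expected_lambda(self) -> float:
        """E[λ] = base × (1 + amplitude × E[events per period])."""
        ev = self.event_rate * PERIOD_SECONDS / 3600.0
        return self.base_intensity * (1.0 + self.activity_amplitude * ev)

    @property
    def lambda_variance(self) -> float:
        """Var(λ) across periods, from the Poisson event count."""
        ev = self.event_rate * PERIOD_SECONDS / 3600.0
        return (self.base_intensity * self.activity_amplitude) ** 2 * ev


@dataclass(frozen=True)
class GroundTruth:
    """Exactly what the generator did, keyed by (surgery_id, period_index)."""

    latent_intensity: Mapping[tuple[str, int], float]
    burst_periods: frozenset[tuple[str, int]]
    discarded: frozenset[tuple[str, int]]
    true_cfu_coupling: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "latent_intensity": {f"{s}:{p}": v for (s, p), v in self.latent_intensity.items()},
            "burst_periods": sorted(f"{s}:{p}" for s, p in self.burst_periods),
            "discarded": sorted(f"{s}:{p}" for s, p in self.discarded),
            "true_cfu_coupling": self.true_cfu_coupling,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


@dataclass(frozen=True)
class SimulatedSession:
    """Generated records, schedule and culture table plus the ground truth."""

    records: Mapping[str, tuple[ParticleRecord, ...]]
    schedule: Mapping[str, tuple[dt.time, ...]]
    cfu: tuple[CfuSample, ...]
    truth: GroundTruth
    config: SessionConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the ingest-dialect CSVs and the ground-truth JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "particles": out / "particles.csv",
            "schedule": out / "schedule.csv",
            "cfu": out / "cfu.csv",
            "truth": out / "ground_truth.json",
        }
        write_particle_sessions(paths["particles"], self.records)
        write_schedule(paths["schedule"], self.schedule)
        write_cfu_samples(paths["cfu"], self.cfu)
        self.truth.to_json(paths["truth"])
        return paths


def _period_start_seconds(period_index: int) -> int:
    t0 = SESSION_START.hour * 3600 + SESSION_START.minute * 60 + SESSION_START.second
    return t0 + (period_index - 1) * (PERIOD_SECONDS + BREAK_SECONDS)


def _records_from_counts(counts: np.ndarray, start_seconds: int) -> list[ParticleRecord]:
    out = []
    for r in range(counts.shape[0]):
        sec = start_seconds + r * RECORD_SECONDS
        t = dt.time(sec // 3600, (sec % 3600) // 60, sec % 60)
        out.append(ParticleRecord(t, {b: int(counts[r, k]) for k, b in enumerate(SIZE_BINS)}))
    return out


def inject_bursts(
    records: Sequence[ParticleRecord],
    schedule: Iterable[tuple[int, int]],
    params: Mapping[SizeBin, float] | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[ParticleRecord]:
    """Add Poisson burst counts to a record sequence at scheduled positions.

    ``schedule`` lists (start_index, n_records) into ``records``; ``params``
    gives the mean added count per 5-s record for each bin.  Counts only
    increase.  An empty schedule returns the records unchanged.
    """
    params = dict(params) if params is not None else dict(DEFAULT_BURST_MEANS)
    if set(params) != set(SIZE_BINS):
        raise SyntheticError("burst params must cover exactly the six size bins")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = list(records)
    means = np.array([params[b] for b in SIZE_BINS], dtype=float)
    for start, n_rec in schedule:
        if start < 0 or n_rec < 0 or start + n_rec > len(out):
            raise SyntheticError(
                f"burst [{start}, {start + n_rec}) outside the {len(out)}-record stream"
            )
        extra = rng.poisson(means, size=(n_rec, len(SIZE_BINS)))
        for r in range(n_rec):
            rec = out[start + r]
            out[start + r] = ParticleRecord(
                rec.timestamp,
                {b: rec.counts[b] + int(extra[r, k]) for k, b in enumerate(SIZE_BINS)},
            )
    return out


def simulate_session(config: SessionConfig, seed: int | None = None) -> SimulatedSession:
    """Generate one study's worth of sessions from a :class:`SessionConfig`.

    All randomness descends from ``seed`` (default ``config.seed``) through
    per-surgery substreams, with separate substreams for burst injection and
    plate discards.  Because bursts draw from their own substream, runs of
    the same seed with and without a burst schedule share identical baseline
    counts and CFU draws — the paired design the exclusion-recovery tests
    rely on.
    """
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(config.n_surgeries + 2)
    burst_rng = np.random.default_rng(children[-2])
    discard_rng = np.random.default_rng(children[-1])

    ids = surgery_ids(config.n_surgeries)
    frac_ge3 = config.frac_ge3
    if frac_ge3 <= 0:
        raise SyntheticError("bin_fractions must give positive mass at >= 3 um")
    bin_means_unit = np.array(
        [config.bin_fractions[b] / frac_ge3 / RECORDS_PER_PERIOD for b in SIZE_BINS]
    )
    ev_per_period = config.event_rate * PERIOD_SECONDS / 3600.0

    records: dict[str, tuple[ParticleRecord, ...]] = {}
    schedule: dict[str, tuple[dt.time, ...]] = {}
    cfu: list[CfuSample] = []
    latent: dict[tuple[str, int], float] = {}
    cfu_counts: dict[tuple[str, int], int] = {}

    for s_idx, sid in enumerate(ids):
        rng = np.random.default_rng(children[s_idx])
        surgery_records: list[ParticleRecord] = []
        starts: list[dt.time] = []
        for p in range(1, config.periods_per_surgery + 1):
            n_events = rng.poisson(ev_per_period)
            lam = config.base_intensity * (1.0 + config.activity_amplitude * n_events)
            counts = rng.poisson(lam * bin_means_unit, size=(RECORDS_PER_PERIOD, len(SIZE_BINS)))
            start_sec = _period_start_seconds(p)
            starts.append(dt.time(start_sec // 3600, (start_sec % 3600) // 60, start_sec % 60))
            surgery_records.extend(_records_from_counts(counts, start_sec))
            latent[(sid, p)] = float(lam)
            cfu_counts[(sid, p)] = int(rng.poisson(config.cfu_coupling * lam))
        records[sid] = tuple(surgery_records)
        schedule[sid] = tuple(starts)

    # burst injection from its own substream, in schedule order
    burst_keys: set[tuple[str, int]] = set()
    for b in config.burst_schedule:
        flat = (b.period_index - 1) * RECORDS_PER_PERIOD + b.start_record
        records[b.surgery_id] = tuple(
            inject_bursts(records[b.surgery_id], [(flat, b.n_records)], config.burst_params, burst_rng)
        )
        burst_keys.add((b.surgery_id, b.period_index))

    # plate discards: scheduled, or Bernoulli per period in fixed order
    if config.discard_schedule is not None:
        discarded = set(config.discard_schedule)
        unknown = discarded - set(latent)
        if unknown:
            raise SyntheticError(f"discard_schedule names unknown periods: {sorted(unknown)}")
    else:
        draws = discard_rng.random(config.n_periods)
        keys = [(sid, p) for sid in ids for p in range(1, config.periods_per_surgery + 1)]
        discarded = {k for k, u in zip(keys, draws) if u < config.discard_probability}

    for sid in ids:
        for p in range(1, config.periods_per_surgery + 1):
            disc = (sid, p) in discarded
            cfu.append(CfuSample(sid, p, None if disc else cfu_counts[(sid, p)], disc))

    truth = GroundTruth(latent, frozenset(burst_keys), frozenset(discarded), config.cfu_coupling)
    return SimulatedSession(records, schedule, tuple(cfu), truth, config)


def study_conditions(seed: int = 0) -> SessionConfig:
    """The configuration mirroring the study's bookkeeping.

    18 surgeries × 6 periods = 108; 8 plates discarded (3 in one surgery,
    2 in one, 1 in two more, plus one further surgery to reach the stated 8);
    4 diathermy bursts — 2 periods in one surgery and 1 in each of two others
    — lasting 16–28 records (1.3–2.3 minutes of sustained diathermy).
    Discards and bursts never hit the same period, so the exclusion groups
    are disjoint.
    """
    bursts = (
        BurstSpec("S05", 2, 30, 24),
        BurstSpec("S05", 4, 60, 16),
        BurstSpec("S09", 3, 45, 20),
        BurstSpec("S14", 5, 20, 28),
    )
    discards = frozenset(
        {
            ("S02", 1),
            ("S02", 3),
            ("S02", 6),
            ("S07", 2),
            ("S07", 5),
            ("S11", 4),
            ("S16", 1),
            ("S18", 6),
        }
    )
    return SessionConfig(burst_schedule=bursts, discard_schedule=discards, seed=seed)
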