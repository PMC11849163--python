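"""Detection of diathermy-induced distortion in bioparticle count series.

Electrosurgical cautery vaporizes tissue and releases a plume of small
fluorescing particles that swamps the optical counter.  The signature, read
off the instrument output, is a sustained run of high counts in the smallest
size channel accompanied, within the same minute, by elevated counts in the
3–<5 µm and 5–<10 µm channels.  A 10-minute period is flagged when all three
requirements hold:

* ≥ 12 continuous 5-second counts of 0.5–<1 µm particles ≥ 10, of which
  at least one count is ≥ 20;
* ≥ 1 count of 3–<5 µm particles ≥ 3 during that run;
* ≥ 1 count of 5–<10 µm particles ≥ 2 during that run.

The rule is pattern-based and post hoc: it flags the measurement artifact,
not the physical cause, and every threshold is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .ingest import SamplingPeriod, SizeBin

__all__ = [
    "DistortionRule",
    "DistortionVerdict",
    "DistortionError",
    "find_runs",
    "classify_period",
    "flag_all",
    "write_verdicts",
    "read_verdicts",
]


class DistortionError(ValueError):
    """Raised for invalid rules or periods the rule cannot be applied to."""


@dataclass(frozen=True)
class DistortionRule:
    """Thresholds of the distortion pattern; defaults are the study rule.

    ``clause_scope`` controls where the mid/large-bin requirements are
    evaluated: ``"run"`` (default) restricts them to the qualifying run's
    records, ``"period"`` accepts a qualifying count anywhere in the
    10-minute period.  The packaged worked example is flagged identically
    under both readings.
    """

    small_bin: SizeBin = SizeBin.B05_1
    run_threshold: int = 10
    run_min_length: int = 12
    peak_threshold: int = 20
    mid_bin: SizeBin = SizeBin.B3_5
    mid_threshold: int = 3
    large_bin: SizeBin = SizeBin.B5_10
    large_threshold: int = 2
    clause_scope: str = "run"

    def __post_init__(self) -> None:
        for name in ("run_threshold", "peak_threshold", "mid_threshold", "large_threshold"):
            if getattr(self, name) < 1:
                raise DistortionError(f"{name} must be a positive integer")
        if self.run_min_length < 1:
            raise DistortionError("run_min_length must be >= 1")
        if self.clause_scope not in {"run", "period"}:
            raise DistortionError(f"clause_scope must be 'run' or 'period', got {self.clause_scope!r}")

    @classmethod
    def from_mapping(cls, data: dict) -> "DistortionRule":
        kwargs = dict(data)
        for key in ("small_bin", "mid_bin", "large_bin"):
            if key in kwargs and not isinstance(kwargs[key], SizeBin):
                kwargs[key] = SizeBin(kwargs[key])
        known = {f.name for f in fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise DistortionError(f"unknown rule fields: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "DistortionRule":
        """Load a rule from a YAML or JSON key-value file."""
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise DistortionError(f"{path}: rule file must hold a mapping")
        return cls.from_mapping(data)


@dataclass(frozen=True)
class DistortionVerdict:
    """Outcome of applying the rule to one period.

    ``qualifying_runs`` holds the half-open record-index intervals that meet
    all three requirements; the period is distorted iff it is non-empty.
    """

    surgery_id: str
    period_index: int
    distorted: bool
    qualifying_runs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.distorted != bool(self.qualifying_runs):
            raise DistortionError("distorted must be true iff qualifying_runs is non-empty")


def find_runs(counts: Sequence[int], threshold: int, min_length: int) -> list[tuple[int, int]]:
    """Maximal runs of consecutive counts ≥ ``threshold`` of length ≥ ``min_length``.

    Returns sorted, non-overlapping half-open index intervals ``[start, end)``.
    """
    runs: list[tuple[int, int]] = []
    start: int | None = None
    for i, c in enumerate(counts):
        if c >= threshold:
            if start is None:
                start = i
        elif start is not None:
            if i - start >= min_length:
                runs.append((start, i))
            start = None
    if start is not None and len(counts) - start >= min_length:
        runs.append((start, len(counts)))
    return runs


def classify_period(
    period: SamplingPeriod, rule: DistortionRule | None = None, *, excerpt: bool = False
) -> DistortionVerdict:
    """Apply the distortion rule to one 10-minute period.

    Partial periods (such as the packaged printed excerpts) are only accepted
    with ``excerpt=True``; the rule then runs on however many records exist.
    """
    rule = rule or DistortionRule()
    if period.partial and not excerpt:
        raise DistortionError(
            f"{period.surgery_id} period {period.period_index} is partial; "
            "pass excerpt=True to classify an excerpt"
        )
    small = period.bin_counts(rule.small_bin)
    mid = period.bin_counts(rule.mid_bin)
    large = period.bin_counts(rule.large_bin)
    qualifying: list[tuple[int, int]] = []
    for start, end in find_runs(small, rule.run_threshold, rule.run_min_length):
        if rule.clause_scope == "run":
            lo, hi = start, end
        else:
            lo, hi = 0, len(small)
        if (
            max(small[start:end]) >= rule.peak_threshold
            and max(mid[lo:hi]) >= rule.mid_threshold
            and max(large[lo:hi]) >= rule.large_threshold
        ):
            qualifying.append((start, end))
    return DistortionVerdict(
        period.surgery_id, period.period_index, bool(qualifying), tuple(qualifying)
    )


def flag_all(
    periods: Iterable[SamplingPeriod],
    rule: DistortionRule | None = None,
    *,
    excerpt: bool = False,
) -> list[DistortionVerdict]:
    """Classify every period, preserving order."""
    rule = rule or DistortionRule()
    return [classify_period(p, rule, excerpt=excerpt) for p in periods]


def write_verdicts(path: str | Path, verdicts: Iterable[DistortionVerdict]) -> None:
    """Write verdicts as CSV ``surgery_id,period_index,distorted,run_starts``."""
    lines = ["surgery_id,period_index,distorted,run_starts"]
    for v in verdicts:
        starts = ";".join(str(s) for s, _ in v.qualifying_runs)
        lines.append(f"{v.surgery_id},{v.period_index},{'true' if v.distorted else 'false'},{starts}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_verdicts(path: str | Path) -> list[DistortionVerdict]:
    """Read a verdict CSV written by :func:`write_verdicts`.

    Run end indices are not stored in the CSV; re-read verdicts carry
    zero-length placeholders for the run spans.
    """
    import pandas as pd

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        distorted = d["distorted"].strip().lower() in {"true", "1", "yes"}
        starts = tuple(int(s) for s in d["run_starts"].split(";") if s != "")
        runs = tuple((s, s) for s in starts) if distorted else ()
        if distorted and not runs:
            runs = ((0, 0),)
        out.append(
            DistortionVerdict(str(d["surgery_id"]), int(d["period_index"]), distorted, runs)
        )
    return out
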