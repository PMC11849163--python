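"""Period totals, FBP–CFU pairing, exclusion bookkeeping and surgery means.

Counts are aggregated over each 10-minute period to fluorescent-bioparticle
totals per 50 dm³ of sampled air, with the ≥3 µm total (the size class the
gelatine filter of the culture sampler retains) as the comparison quantity.
Pairs are joined to the culture results on (surgery, period index) — the two
instruments sample in the same slot, so the join is by slot, not by clock —
and carry an exclusion status: a discarded culture plate or a distortion
verdict removes the pair from the analysis set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .distortion import DistortionVerdict
from .ingest import GE3_BINS, SIZE_BINS, CfuSample, SamplingPeriod, SizeBin, sampled_volume_dm3

__all__ = [
    "EXCLUDE_NONE",
    "EXCLUDE_CFU",
    "EXCLUDE_DISTORTED",
    "PeriodFbp",
    "PairedMeasurement",
    "SurgeryMeans",
    "AggregateError",
    "JoinError",
    "period_fbp",
    "fbp_per_m3",
    "pair_and_exclude",
    "analysis_pairs",
    "surgery_means",
    "write_pairs",
    "read_pairs",
]

EXCLUDE_NONE = "none"
EXCLUDE_CFU = "cfu_discarded"
EXCLUDE_DISTORTED = "distorted"


class AggregateError(ValueError):
    """Raised for aggregation on inputs violating preconditions."""


class JoinError(AggregateError):
    """Raised when FBP periods, CFU samples and verdicts do not align."""


@dataclass(frozen=True)
class PeriodFbp:
    """Per-period particle totals (counts per 50 dm³ for a complete period)."""

    surgery_id: str
    period_index: int
    per_bin_totals: Mapping[SizeBin, int]
    fbp_ge3: int
    n_records: int

    @property
    def volume_dm3(self) -> float:
        """Air volume actually sampled (50 dm³ for a complete period)."""
        return sampled_volume_dm3(self.n_records)


@dataclass(frozen=True)
class PairedMeasurement:
    """One period's (FBP ≥3 µm per 50 dm³, CFU per m³) pair with exclusion status."""

    surgery_id: str
    period_index: int
    fbp_ge3: int
    cfu_per_m3: int | None
    excluded: str = EXCLUDE_NONE

    def __post_init__(self) -> None:
        if self.excluded not in {EXCLUDE_NONE, EXCLUDE_CFU, EXCLUDE_DISTORTED}:
            raise AggregateError(f"unknown exclusion label {self.excluded!r}")
        if self.excluded == EXCLUDE_NONE and self.cfu_per_m3 is None:
            raise AggregateError("non-excluded pair must carry a CFU count")


@dataclass(frozen=True)
class SurgeryMeans:
    """Per-surgery arithmetic means over the non-excluded periods."""

    surgery_id: str
    mean_fbp_ge3: float
    mean_cfu: float
    n_periods_used: int


def period_fbp(period: SamplingPeriod, *, excerpt: bool = False) -> PeriodFbp:
    """Sum the 5-second counts of one period into per-bin 10-minute totals.

    ``fbp_ge3`` is the total over the 3–<5, 5–<10 and ≥10 µm bins.  Partial
    periods (printed excerpts) are only accepted with ``excerpt=True``; their
    totals then cover a partial sampled volume, reported via ``n_records``.
    """
    if period.partial and not excerpt:
        raise AggregateError(
            f"{period.surgery_id} period {period.period_index} is partial; "
            "pass excerpt=True to total an excerpt"
        )
    totals = {b: sum(period.bin_counts(b)) for b in SIZE_BINS}
    return PeriodFbp(
        period.surgery_id,
        period.period_index,
        totals,
        sum(totals[b] for b in GE3_BINS),
        len(period.records),
    )


def fbp_per_m3(fbp_per_50dm3: float) -> float:
    """Convert a per-50 dm³ count to a per-m³ rate (×20).

    Provided for unit comparisons only; the default pipeline correlates the
    raw per-50 dm³ and per-m³ scales against each other, as the instruments
    report them.
    """
    return fbp_per_50dm3 * 20.0


def _key(obj) -> tuple[str, int]:
    return (obj.surgery_id, obj.period_index)


def pair_and_exclude(
    fbps: Sequence[PeriodFbp],
    cfus: Sequence[CfuSample],
    verdicts: Sequence[DistortionVerdict] | None = None,
) -> list[PairedMeasurement]:
    """Join period totals with culture samples and label exclusions.

    The join key is (surgery_id, period_index) and must match one-to-one;
    orphans on either side raise :class:`JoinError`.  A discarded plate
    labels the pair ``cfu_discarded``; a distortion verdict labels it
    ``distorted``; when both apply the plate discard takes precedence (the
    two exclusion groups are reported as disjoint).  Passing ``verdicts=None``
    skips distortion exclusion entirely (the distortion-retained analysis).
    """
    cfu_by_key = {_key(c): c for c in cfus}
    if len(cfu_by_key) != len(cfus):
        raise JoinError("duplicate (surgery_id, period_index) keys in CFU table")
    fbp_keys = [_key(f) for f in fbps]
    if len(set(fbp_keys)) != len(fbp_keys):
        raise JoinError("duplicate (surgery_id, period_index) keys in FBP periods")
    orphans_fbp = sorted(set(fbp_keys) - set(cfu_by_key))
    orphans_cfu = sorted(set(cfu_by_key) - set(fbp_keys))
    if orphans_fbp or orphans_cfu:
        raise JoinError(
            f"unmatched keys — FBP without CFU: {orphans_fbp}; CFU without FBP: {orphans_cfu}"
        )
    distorted_keys: set[tuple[str, int]] = set()
    if verdicts is not None:
        verdict_keys = {_key(v) for v in verdicts}
        missing = sorted(set(fbp_keys) - verdict_keys)
        if missing:
            raise JoinError(f"periods without a distortion verdict: {missing}")
        distorted_keys = {_key(v) for v in verdicts if v.distorted}
    pairs: list[PairedMeasurement] = []
    for f in fbps:
        c = cfu_by_key[_key(f)]
        if c.discarded:
            label = EXCLUDE_CFU
        elif _key(f) in distorted_keys:
            label = EXCLUDE_DISTORTED
        else:
            label = EXCLUDE_NONE
        pairs.append(PairedMeasurement(f.surgery_id, f.period_index, f.fbp_ge3, c.cfu_per_m3, label))
    return pairs


def analysis_pairs(pairs: Iterable[PairedMeasurement]) -> list[PairedMeasurement]:
    """The non-excluded subsequence — the dataset all statistics run on."""
    return [p for p in pairs if p.excluded == EXCLUDE_NONE]


def surgery_means(pairs: Sequence[PairedMeasurement]) -> list[SurgeryMeans]:
    """Arithmetic per-surgery means of FBP ≥3 µm and CFU over usable periods.

    Surgeries whose periods are all excluded are omitted with a warning.
    Output order follows first appearance in the input.
    """
    order: list[str] = []
    groups: dict[str, list[PairedMeasurement]] = {}
    for p in pairs:
        if p.surgery_id not in groups:
            order.append(p.surgery_id)
            groups[p.surgery_id] = []
        if p.excluded == EXCLUDE_NONE:
            groups[p.surgery_id].append(p)
    out: list[SurgeryMeans] = []
    for sid in order:
        used = groups[sid]
        if not used:
            warnings.warn(f"surgery {sid}: no usable periods, omitted from means", stacklevel=2)
            continue
        out.append(
            SurgeryMeans(
                sid,
                sum(p.fbp_ge3 for p in used) / len(used),
                sum(p.cfu_per_m3 for p in used) / len(used),
                len(used),
            )
        )
    return out


def write_pairs(path: str | Path, pairs: Iterable[PairedMeasurement]) -> None:
    """Write pairs as CSV ``surgery_id,period_index,fbp_ge3_per50dm3,cfu_per_m3,excluded``."""
    lines = ["surgery_id,period_index,fbp_ge3_per50dm3,cfu_per_m3,excluded"]
    for p in pairs:
        cfu = "" if p.cfu_per_m3 is None else str(p.cfu_per_m3)
        lines.append(f"{p.surgery_id},{p.period_index},{p.fbp_ge3},{cfu},{p.excluded}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pairs(path: str | Path) -> list[PairedMeasurement]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        cfu = None if d["cfu_per_m3"].strip() == "" else int(d["cfu_per_m3"])
        out.append(
            PairedMeasurement(
                str(d["surgery_id"]),
                int(d["period_index"]),
                int(d["fbp_ge3_per50dm3"]),
                cfu,
                d["excluded"].strip() or EXCLUDE_NONE,
            )
        )
    return out
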