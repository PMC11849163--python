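"""End-to-end orchestration: simulate or ingest, detect distortion, pair,
apply exclusions, and compute the method-comparison statistics.

The report always carries both the distortion-excluded and the
distortion-retained analyses, at period level and at surgery level — the
contrast between them is the pipeline's central output.  Every excluded
period is logged individually with its reason, so the exclusion bookkeeping
(total − discarded − distorted = analyzed) is auditable.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict

from . import aggregate as agg
from . import stats as st
from .distortion import DistortionRule, flag_all, write_verdicts
from .ingest import (
    CfuSample,
    ParticleRecord,
    read_cfu_samples,
    read_particle_sessions,
    read_schedule,
    segment_sessions,
)
from .synthetic import SessionConfig, SizeBin, BurstSpec, simulate_session

__all__ = [
    "PipelineConfig",
    "AnalysisReport",
    "run_pipeline",
    "load_report_schema",
]

logger = logging.getLogger("orair")


# ---------------------------------------------------------------------------
# report model (pydantic v2); the shipped JSON schema is generated from it

class SpearmanModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    r: Optional[float]
    n: int
    ci_low: Optional[float]
    ci_high: Optional[float]
    level: float


class PassingBablokModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    slope: Optional[float]
    intercept: Optional[float]
    slope_ci_low: Optional[float]
    slope_ci_high: Optional[float]
    n_pairs: int
    n_slopes: int
    k_offset: int
    level: float


class LevelAnalysis(BaseModel):
    model_config = ConfigDict(extra="forbid")
    spearman: SpearmanModel
    passing_bablok: PassingBablokModel


class CrosstabModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    quartile: str
    n_in_quartile: int
    thresholds: list[int]
    fractions: list[float]


class AnalysisReport(BaseModel):
    """Machine-readable pipeline output mirroring the exclusion flowchart."""

    model_config = ConfigDict(extra="forbid")
    n_total_periods: int
    n_cfu_discarded: int
    n_distorted: int
    n_analyzed: int
    period_level_excluded: LevelAnalysis
    period_level_retained: LevelAnalysis
    surgery_level_excluded: LevelAnalysis
    surgery_level_retained: LevelAnalysis
    crosstab_lowest: CrosstabModel
    crosstab_highest: CrosstabModel


def _none_if_nan(x: float) -> Optional[float]:
    return None if x is None or not math.isfinite(x) else float(x)


def _spearman_model(res: st.SpearmanResult) -> SpearmanModel:
    return SpearmanModel(
        r=_none_if_nan(res.r),
        n=res.n,
        ci_low=_none_if_nan(res.ci_low),
        ci_high=_none_if_nan(res.ci_high),
        level=res.level,
    )


def _pb_model(fit: st.PassingBablokFit) -> PassingBablokModel:
    return PassingBablokModel(
        slope=_none_if_nan(fit.slope),
        intercept=_none_if_nan(fit.intercept),
        slope_ci_low=_none_if_nan(fit.slope_ci_low),
        slope_ci_high=_none_if_nan(fit.slope_ci_high),
        n_pairs=fit.n_pairs,
        n_slopes=fit.n_slopes,
        k_offset=fit.k_offset,
        level=fit.level,
    )


def load_report_schema() -> dict:
    """The JSON schema shipped with the package for :class:`AnalysisReport`."""
    from importlib.resources import files

    with (files("orair.data") / "report.schema.json").open() as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# pipeline configuration

@dataclass
class PipelineConfig:
    """Inputs for one pipeline run: either a simulation or three CSV paths."""

    simulate: SessionConfig | None = None
    particles: Path | None = None
    schedule: Path | None = None
    cfu: Path | None = None
    rule: DistortionRule = field(default_factory=DistortionRule)
    level: float = 0.95
    thresholds: tuple[int, ...] = (5, 10)

    def __post_init__(self) -> None:
        has_paths = self.particles or self.schedule or self.cfu
        if self.simulate is not None and has_paths:
            raise ValueError("give either a simulation config or input paths, not both")
        if self.simulate is None and not (self.particles and self.schedule and self.cfu):
            raise ValueError("need particles, schedule and cfu paths (or a simulation config)")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from a YAML/JSON file.

        Recognized keys: ``simulate`` (SessionConfig fields, with size-bin
        maps keyed by column label and burst entries as
        ``[surgery_id, period_index, start_record, n_records]``),
        ``particles``/``schedule``/``cfu`` paths, ``rule`` (DistortionRule
        fields), ``level`` and ``thresholds``.
        """
        data = yaml.safe_load(Path(path).read_text()) or {}
        base = Path(path).parent
        kwargs: dict = {}
        if "simulate" in data and data["simulate"] is not None:
            kwargs["simulate"] = _session_config_from_mapping(data["simulate"])
        for key in ("particles", "schedule", "cfu"):
            if data.get(key):
                p = Path(data[key])
                kwargs[key] = p if p.is_absolute() else base / p
        if "rule" in data and data["rule"] is not None:
            kwargs["rule"] = DistortionRule.from_mapping(data["rule"])
        if "level" in data:
            kwargs["level"] = float(data["level"])
        if "thresholds" in data:
            kwargs["thresholds"] = tuple(int(t) for t in data["thresholds"])
        return cls(**kwargs)


def _session_config_from_mapping(data: Mapping) -> SessionConfig:
    kwargs = dict(data)
    for key in ("bin_fractions", "burst_params"):
        if key in kwargs:
            kwargs[key] = {SizeBin(k): float(v) for k, v in kwargs[key].items()}
    if "burst_schedule" in kwargs:
        kwargs["burst_schedule"] = tuple(
            BurstSpec(str(b[0]), int(b[1]), int(b[2]), int(b[3])) for b in kwargs["burst_schedule"]
        )
    if "discard_schedule" in kwargs and kwargs["discard_schedule"] is not None:
        kwargs["discard_schedule"] = frozenset(
            (str(s), int(p)) for s, p in kwargs["discard_schedule"]
        )
    return SessionConfig(**kwargs)


# ---------------------------------------------------------------------------
# pipeline

def _level_analysis(x: Sequence[float], y: Sequence[float], level: float) -> LevelAnalysis:
    return LevelAnalysis(
        spearman=_spearman_model(st.spearman(x, y, level)),
        passing_bablok=_pb_model(st.passing_bablok(x, y, level)),
    )


def _pairs_analysis(pairs: Sequence[agg.PairedMeasurement], level: float) -> LevelAnalysis:
    used = agg.analysis_pairs(pairs)
    return _level_analysis([p.fbp_ge3 for p in used], [p.cfu_per_m3 for p in used], level)


def _means_analysis(pairs: Sequence[agg.PairedMeasurement], level: float) -> LevelAnalysis:
    means = agg.surgery_means(pairs)
    return _level_analysis(
        [m.mean_fbp_ge3 for m in means], [m.mean_cfu for m in means], level
    )


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> AnalysisReport:
    """Run the full comparison and return the :class:`AnalysisReport`.

    With ``out_dir`` set, intermediate tables (verdicts, pairs) and the
    report JSON are written there; a simulation run also writes its
    generated inputs and ground truth.  ``seed`` overrides the simulation
    config's seed and is ignored for file inputs.
    """
    if config.simulate is not None:
        session = simulate_session(config.simulate, seed=seed)
        records, schedule, cfu = session.records, session.schedule, list(session.cfu)
        if out_dir is not None:
            session.write(out_dir)
    else:
        records = read_particle_sessions(config.particles)
        schedule = read_schedule(config.schedule)
        cfu = read_cfu_samples(config.cfu, max_period=max(len(v) for v in schedule.values()))

    periods = segment_sessions(records, schedule)
    verdicts = flag_all(periods, config.rule)
    fbps = [agg.period_fbp(p) for p in periods]

    pairs_excluded = agg.pair_and_exclude(fbps, cfu, verdicts)
    pairs_retained = agg.pair_and_exclude(fbps, cfu, None)

    for p in pairs_excluded:
        if p.excluded != agg.EXCLUDE_NONE:
            logger.info(
                "excluded %s period %d: %s", p.surgery_id, p.period_index, p.excluded
            )

    n_total = len(pairs_excluded)
    n_disc = sum(p.excluded == agg.EXCLUDE_CFU for p in pairs_excluded)
    n_dist = sum(p.excluded == agg.EXCLUDE_DISTORTED for p in pairs_excluded)
    analyzed = agg.analysis_pairs(pairs_excluded)

    report = AnalysisReport(
        n_total_periods=n_total,
        n_cfu_discarded=n_disc,
        n_distorted=n_dist,
        n_analyzed=len(analyzed),
        period_level_excluded=_pairs_analysis(pairs_excluded, config.level),
        period_level_retained=_pairs_analysis(pairs_retained, config.level),
        surgery_level_excluded=_means_analysis(pairs_excluded, config.level),
        surgery_level_retained=_means_analysis(pairs_retained, config.level),
        crosstab_lowest=_crosstab_model(analyzed, "lowest", config.thresholds),
        crosstab_highest=_crosstab_model(analyzed, "highest", config.thresholds),
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_verdicts(out / "verdicts.csv", verdicts)
        agg.write_pairs(out / "pairs.csv", pairs_excluded)
        (out / "report.json").write_text(report.model_dump_json(indent=2) + "\n")
    return report


def _crosstab_model(
    pairs: Sequence[agg.PairedMeasurement], which: str, thresholds: Sequence[int]
) -> CrosstabModel:
    ct = st.quartile_crosstab(pairs, which, thresholds)
    return CrosstabModel(
        quartile=ct.quartile,
        n_in_quartile=ct.n_in_quartile,
        thresholds=list(ct.thresholds),
        fractions=list(ct.fractions),
    )
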