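"""The session generator: reproducibility, calibration and burst injection."""

import math

import numpy as np
import pytest

from orair.aggregate import analysis_pairs, pair_and_exclude, period_fbp
from orair.distortion import classify_period, flag_all
from orair.ingest import (
    RECORDS_PER_PERIOD,
    SIZE_BINS,
    read_cfu_samples,
    read_particle_sessions,
    read_schedule,
    segment_sessions,
    write_cfu_samples,
    write_particle_sessions,
    write_schedule,
)
from orair.stats import spearman
from orair.synthetic import (
    BurstSpec,
    SessionConfig,
    SyntheticError,
    inject_bursts,
    simulate_session,
    study_conditions,
    surgery_ids,
)


def small_config(**kw):
    defaults = dict(n_surgeries=2, periods_per_surgery=2, seed=5)
    defaults.update(kw)
    return SessionConfig(**defaults)


def period_pairs(session):
    """(fbp_ge3, cfu) analysis pairs for a simulated session."""
    periods = segment_sessions(session.records, session.schedule)
    fbps = [period_fbp(p) for p in periods]
    verdicts = flag_all(periods)
    return pair_and_exclude(fbps, list(session.cfu), verdicts)


def test_zero_intensity_yields_all_zero():
    session = simulate_session(small_config(base_intensity=0.0))
    for records in session.records.values():
        assert all(c == 0 for r in records for c in r.counts.values())
    assert all(s.cfu_per_m3 == 0 for s in session.cfu)


def test_reproducibility_identical_seed():
    a = simulate_session(study_conditions(), seed=42)
    b = simulate_session(study_conditions(), seed=42)
    assert a.records == b.records and a.cfu == b.cfu and a.truth == b.truth
    c = simulate_session(study_conditions(), seed=43)
    assert c.records != a.records


def test_mean_fbp_matches_configured_expectation():
    config = SessionConfig(seed=2)
    session = simulate_session(config)
    periods = segment_sessions(session.records, session.schedule)
    fbp = np.array([period_fbp(p).fbp_ge3 for p in periods])
    assert fbp.size == 108
    # fbp_ge3 | lambda ~ Poisson(lambda): mean E[lambda], variance
    # E[lambda] + Var(lambda); the observed mean must sit within 3 SE
    expected = config.expected_lambda
    se = math.sqrt((config.expected_lambda + config.lambda_variance) / fbp.size)
    assert abs(fbp.mean() - expected) <= 3 * se


def test_discard_probability_one_discards_everything():
    session = simulate_session(small_config(discard_probability=1.0))
    assert all(s.discarded for s in session.cfu)
    assert len(session.truth.discarded) == 4


def test_scheduled_discards_and_bursts_recorded_in_truth():
    session = simulate_session(study_conditions(), seed=9)
    assert session.truth.discarded == study_conditions().discard_schedule
    assert session.truth.burst_periods == {("S05", 2), ("S05", 4), ("S09", 3), ("S14", 5)}
    assert len(session.cfu) == 108
    discarded = {(s.surgery_id, s.period_index) for s in session.cfu if s.discarded}
    assert discarded == session.truth.discarded


def test_inject_bursts_identity_and_bounds():
    session = simulate_session(small_config())
    records = list(session.records["S01"])
    assert inject_bursts(records, [], rng=0) == records
    with pytest.raises(SyntheticError, match="outside"):
        inject_bursts(records, [(len(records) - 5, 10)], rng=0)


def test_inject_bursts_only_increases_counts():
    session = simulate_session(small_config())
    records = list(session.records["S01"])
    bursted = inject_bursts(records, [(10, 20)], rng=1)
    for before, after in zip(records, bursted):
        assert all(after.counts[b] >= before.counts[b] for b in SIZE_BINS)
        assert after.timestamp == before.timestamp


def test_long_burst_is_flagged_and_short_burst_is_not():
    config = small_config(n_surgeries=1, periods_per_surgery=1)
    base = simulate_session(config)
    records = list(base.records["S01"])
    flagged = inject_bursts(records, [(30, 16)], rng=3)
    period = segment_sessions({"S01": flagged}, base.schedule)[0]
    assert classify_period(period).distorted
    short = inject_bursts(records, [(30, 5)], rng=3)
    period_short = segment_sessions({"S01": short}, base.schedule)[0]
    assert not classify_period(period_short).distorted


def test_burst_substream_leaves_baseline_draws_unchanged():
    """Same seed with and without bursts gives identical non-burst data."""
    clean = simulate_session(SessionConfig(discard_probability=0.0), seed=6)
    burst_cfg = study_conditions()
    bursty = simulate_session(
        SessionConfig(burst_schedule=burst_cfg.burst_schedule, discard_probability=0.0),
        seed=6,
    )
    assert bursty.cfu == clean.cfu
    burst_surgeries = {b.surgery_id for b in burst_cfg.burst_schedule}
    for sid in surgery_ids(18):
        if sid not in burst_surgeries:
            assert bursty.records[sid] == clean.records[sid]


def test_coupling_recovery_spearman_above_threshold():
    """Shared latent intensity induces r > 0.6 between FBP and CFU."""
    rs = []
    for seed in range(20):
        session = simulate_session(SessionConfig(discard_probability=0.0), seed=seed)
        pairs = analysis_pairs(period_pairs(session))
        rs.append(spearman([p.fbp_ge3 for p in pairs], [p.cfu_per_m3 for p in pairs]).r)
    assert np.mean(rs) > 0.6


def test_round_trip_through_csv_dialect(tmp_path):
    session = simulate_session(small_config())
    write_particle_sessions(tmp_path / "p.csv", session.records)
    write_schedule(tmp_path / "s.csv", session.schedule)
    write_cfu_samples(tmp_path / "c.csv", session.cfu)
    records = read_particle_sessions(tmp_path / "p.csv")
    assert {k: tuple(v) for k, v in records.items()} == dict(session.records)
    schedule = read_schedule(tmp_path / "s.csv")
    assert {k: tuple(v) for k, v in schedule.items()} == dict(session.schedule)
    assert tuple(read_cfu_samples(tmp_path / "c.csv")) == session.cfu


def test_config_validation():
    with pytest.raises(SyntheticError, match="sum to 1"):
        SessionConfig(bin_fractions={b: 0.5 for b in SIZE_BINS})
    with pytest.raises(SyntheticError, match="exceeds"):
        SessionConfig(burst_schedule=(BurstSpec("S01", 1, 110, 20),))
    with pytest.raises(SyntheticError, match="unknown surgery"):
        SessionConfig(n_surgeries=2, burst_schedule=(BurstSpec("S09", 1, 0, 12),))
    with pytest.raises(SyntheticError, match="discard_probability"):
        SessionConfig(discard_probability=1.5)
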