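"""Spearman/Fisher, Passing–Bablok (against an exhaustive oracle) and crosstabs."""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as hst

from orair.aggregate import EXCLUDE_CFU, PairedMeasurement
from orair.stats import (
    StatsError,
    fisher_ci,
    midranks,
    passing_bablok,
    quartile_crosstab,
    round_half_away,
    spearman,
)


# ---------------------------------------------------------------------------
# independent Passing-Bablok oracle: plain-python exhaustive enumeration

def pb_oracle(x, y, level=0.95):
    """List every pairwise slope, discard -1, count K, take the shifted median."""
    n = len(x)
    slopes = []
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[j] - x[i], y[j] - y[i]
            if dx == 0 and dy == 0:
                continue
            s = dy / dx if dx != 0 else math.copysign(math.inf, dy)
            if s != -1.0:
                slopes.append(s)
    slopes.sort()
    N = len(slopes)
    K = sum(1 for s in slopes if s < -1.0)

    def ostat(rank):  # 1-based, clipped
        return slopes[min(max(rank, 1), N) - 1]

    if N % 2 == 1:
        b = ostat((N + 1) // 2 + K)
    else:
        b = 0.5 * (ostat(N // 2 + K) + ostat(N // 2 + 1 + K))
    z = scipy.stats.norm.ppf((1 + level) / 2)
    C = z * math.sqrt(n * (n - 1) * (2 * n + 5) / 18)
    M1 = math.ceil((N - C) / 2)
    lo, hi = ostat(M1 + K), ostat(N - M1 + 1 + K)
    a = math.nan
    if math.isfinite(b):
        resid = sorted(yi - b * xi for xi, yi in zip(x, y))
        m = len(resid)
        a = resid[m // 2] if m % 2 == 1 else 0.5 * (resid[m // 2 - 1] + resid[m // 2])
    return b, a, lo, hi, N, K


# ---------------------------------------------------------------------------
# midranks

@pytest.mark.parametrize(
    "values, expected",
    [
        ((3, 1, 2), [3, 1, 2]),
        ((5, 5, 1), [2.5, 2.5, 1]),
        ((1, 1, 1, 1), [2.5, 2.5, 2.5, 2.5]),
    ],
)
def test_midranks_examples(values, expected):
    assert midranks(values).tolist() == expected


@given(hst.lists(hst.integers(0, 5), min_size=1, max_size=40))
def test_midranks_sum_identity_and_scipy_agreement(values):
    ranks = midranks(values)
    n = len(values)
    assert float(ranks.sum()) == pytest.approx(n * (n + 1) / 2)
    np.testing.assert_allclose(ranks, scipy.stats.rankdata(values, method="average"))


# ---------------------------------------------------------------------------
# Spearman + Fisher CI

def test_fisher_ci_reference_interval():
    lo, hi = fisher_ci(0.87, 18)
    assert (round_half_away(lo), round_half_away(hi)) == (0.68, 0.95)


def test_fisher_ci_contains_r_and_narrows_with_n():
    for n in (5, 10, 50, 500):
        lo, hi = fisher_ci(0.4, n)
        assert lo < 0.4 < hi
    widths = [np.diff(fisher_ci(0.4, n))[0] for n in (5, 10, 50, 500)]
    assert all(a > b for a, b in zip(widths, widths[1:]))


def test_spearman_perfect_monotone():
    x = list(range(10))
    assert spearman(x, [v**3 + 1 for v in x]).r == pytest.approx(1.0)
    assert spearman(x, [-v for v in x]).r == pytest.approx(-1.0)


def test_spearman_constant_input_flagged():
    res = spearman([1, 1, 1, 1], [1, 2, 3, 4])
    assert res.undefined and math.isnan(res.r)


def test_spearman_matches_scipy():
    rng = np.random.default_rng(7)
    x = rng.poisson(12, size=60)
    y = rng.poisson(8, size=60)
    mine = spearman(x, y)
    ref = scipy.stats.spearmanr(x, y).statistic
    assert mine.r == pytest.approx(ref, abs=1e-12)
    assert mine.ci_low <= mine.r <= mine.ci_high


@given(
    hst.lists(
        hst.tuples(hst.integers(0, 30), hst.integers(0, 30)), min_size=5, max_size=40
    )
)
def test_spearman_invariant_under_monotone_transforms(pairs):
    x = [p[0] for p in pairs]
    y = [p[1] for p in pairs]
    a = spearman(x, y)
    b = spearman([math.exp(v / 10) for v in x], [v**3 for v in y])
    if a.undefined:
        assert b.undefined
    else:
        assert b.r == pytest.approx(a.r, abs=1e-12)


# ---------------------------------------------------------------------------
# Passing-Bablok

def test_passing_bablok_identity_line():
    fit = passing_bablok([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
    assert fit.slope == 1.0 and fit.intercept == 0.0


def test_passing_bablok_exact_affine():
    fit = passing_bablok([1, 2, 3, 4], [3, 5, 7, 9])
    assert fit.slope == 2.0 and fit.intercept == 1.0
    assert fit.n_slopes == 6 and fit.k_offset == 0


def test_passing_bablok_worked_example_matches_oracle():
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    y = [2.0, 1.0, 5.0, 4.0, 7.0]
    fit = passing_bablok(x, y)
    b, a, lo, hi, N, K = pb_oracle(x, y)
    assert (fit.slope, fit.intercept) == (b, a)
    assert (fit.slope_ci_low, fit.slope_ci_high) == (lo, hi)
    assert (fit.n_slopes, fit.k_offset) == (N, K)


@given(
    hst.lists(
        hst.tuples(hst.integers(0, 12), hst.integers(-6, 12)), min_size=3, max_size=12
    ).filter(lambda ps: len({p[0] for p in ps}) > 1)
)
@settings(max_examples=300)
def test_passing_bablok_equals_oracle(pairs):
    x = [float(p[0]) for p in pairs]
    y = [float(p[1]) for p in pairs]
    try:
        b, a, lo, hi, N, K = pb_oracle(x, y)
    except IndexError:
        # every pairwise slope discarded (all exactly -1): no estimate exists
        with pytest.raises(StatsError):
            passing_bablok(x, y)
        return
    fit = passing_bablok(x, y)
    assert fit.n_slopes == N and fit.k_offset == K
    assert fit.slope == b
    if math.isfinite(b):
        assert fit.intercept == a
    assert fit.slope_ci_low == lo and fit.slope_ci_high == hi


@given(
    hst.integers(1, 50),
    hst.integers(-20, 20),
    hst.lists(hst.integers(0, 100), min_size=4, max_size=15, unique=True),
)
def test_passing_bablok_recovers_noiseless_affine(b10, a, xs):
    b = b10 / 10.0
    x = [float(v) for v in xs]
    y = [a + b * v for v in x]
    fit = passing_bablok(x, y)
    assert fit.slope == pytest.approx(b, abs=1e-12)
    assert fit.intercept == pytest.approx(a, abs=1e-9)


def test_passing_bablok_scale_equivariance():
    """Scaling y by c > 0 scales slope and intercept by c.

    Exact as long as no pairwise slope crosses the -1 discard/offset
    threshold under the scaling (the K offset is then unchanged), which
    holds whenever the two methods agree monotonically - all pairwise
    slopes >= 0, the regime the estimator is designed for.
    """
    rng = np.random.default_rng(3)
    x = np.sort(rng.uniform(0, 50, size=20))
    y = np.cumsum(rng.uniform(0, 3, size=20))  # nondecreasing in x
    fit = passing_bablok(x, y)
    scaled = passing_bablok(x, 3.0 * y)
    assert scaled.k_offset == fit.k_offset == 0
    assert scaled.slope == pytest.approx(3.0 * fit.slope)
    assert scaled.intercept == pytest.approx(3.0 * fit.intercept)


def test_passing_bablok_degenerate_inputs():
    with pytest.raises(StatsError):
        passing_bablok([1, 2], [1, 2])
    with pytest.raises(StatsError):
        passing_bablok([2, 2, 2], [1, 2, 3])


# ---------------------------------------------------------------------------
# quartile crosstab

def _pairs(fbp_cfu):
    return [PairedMeasurement("S01", i + 1, f, c) for i, (f, c) in enumerate(fbp_cfu)]


def test_quartile_crosstab_constructed_example():
    pairs = _pairs([(i, i) for i in range(1, 9)])
    low = quartile_crosstab(pairs, "lowest", [5, 10])
    high = quartile_crosstab(pairs, "highest", [5, 10])
    assert low.n_in_quartile == high.n_in_quartile == 2
    assert (low.frac_cfu_ge5, low.frac_cfu_ge10) == (0.0, 0.0)
    assert (high.frac_cfu_ge5, high.frac_cfu_ge10) == (1.0, 0.0)


def test_quartile_crosstab_nested_thresholds():
    rng = np.random.default_rng(11)
    pairs = _pairs(zip(rng.poisson(20, 96), rng.poisson(6, 96)))
    for which in ("lowest", "highest"):
        ct = quartile_crosstab(pairs, which)
        assert ct.frac_cfu_ge10 <= ct.frac_cfu_ge5
        assert ct.n_in_quartile == 24


def test_quartile_crosstab_rejects_bad_input():
    with pytest.raises(StatsError, match="n >= 4"):
        quartile_crosstab(_pairs([(1, 1), (2, 2), (3, 3)]), "lowest")
    bad = _pairs([(i, i) for i in range(1, 9)])
    bad[0] = PairedMeasurement("S01", 1, 1, None, EXCLUDE_CFU)
    with pytest.raises(StatsError, match="non-excluded"):
        quartile_crosstab(bad, "lowest")
    with pytest.raises(StatsError, match="which"):
        quartile_crosstab(_pairs([(i, i) for i in range(8)]), "middle")


def test_round_half_away():
    assert round_half_away(0.675) == 0.68
    assert round_half_away(-0.675) == -0.68
    assert round_half_away(0.674999) == 0.67
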