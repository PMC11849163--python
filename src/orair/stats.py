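"""Method-comparison statistics: Spearman rank correlation with a Fisher-z
confidence interval, Passing–Bablok nonparametric regression, and the
quartile/CFU-threshold cross-tabulation.

These are implemented from first principles because their exact conventions
are the point of the comparison:

* Spearman's r is the product-moment correlation of midranks; its CI is the
  Fisher transform interval tanh(atanh(r) ± z·(n−3)^{-1/2}).
* The Passing–Bablok slope is the shifted median of all pairwise slopes
  S_ij = (y_j − y_i)/(x_j − x_i), i < j: slopes equal to −1 are discarded,
  K = #{slopes < −1} offsets the median index, and the slope CI is read off
  the order statistics at rank-test positions.  The estimator assumes a
  positive relation between the methods and is robust to measurement error
  in both axes and to outliers.
* The cross-tab reports, within the lowest/highest quartile of FBP values,
  the fraction of paired CFU results at or above fixed cutoffs (5, 10
  CFU/m³ by default) — the "low FBP indicates low CFU" summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .aggregate import EXCLUDE_NONE, PairedMeasurement

__all__ = [
    "StatsError",
    "midranks",
    "fisher_ci",
    "SpearmanResult",
    "spearman",
    "PassingBablokFit",
    "passing_bablok",
    "QuartileCrosstab",
    "quartile_crosstab",
    "round_half_away",
]


class StatsError(ValueError):
    """Raised when a statistic's preconditions are not met."""


def midranks(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with ties assigned the mean of the ranks they span.

    Rank sums are always n(n+1)/2, so rank-based statistics are unaffected
    by how ties are ordered in the input.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise StatsError("midranks of an empty sequence")
    order = np.argsort(v, kind="stable")
    ranks = np.empty(v.size, dtype=float)
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and v[order[j + 1]] == v[order[i]]:
            j += 1
        # positions i..j (0-based) share ranks i+1..j+1; assign their mean
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a correlation coefficient.

    tanh(atanh(r) ± z_{(1+level)/2} / sqrt(n−3)); requires n > 3 and |r| < 1.
    """
    if n <= 3:
        raise StatsError("Fisher CI requires n > 3")
    if not -1.0 < r < 1.0:
        raise StatsError("Fisher CI requires |r| < 1")
    z = norm.ppf((1.0 + level) / 2.0)
    half = z / math.sqrt(n - 3)
    zr = math.atanh(r)
    return math.tanh(zr - half), math.tanh(zr + half)


@dataclass(frozen=True)
class SpearmanResult:
    """Spearman correlation with its Fisher-z interval.

    ``undefined`` is set (and ``r`` is NaN) when either variable is constant.
    The CI bounds are NaN for n ≤ 3, where the Fisher interval does not exist.
    """

    r: float
    n: int
    ci_low: float
    ci_high: float
    level: float = 0.95
    undefined: bool = False


def spearman(x: Sequence[float], y: Sequence[float], level: float = 0.95) -> SpearmanResult:
    """Spearman rank correlation of two paired samples.

    r is the Pearson correlation of the midranks, which handles ties in
    count data exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("x and y must be equal-length 1-d sequences")
    n = x.size
    if n < 2:
        raise StatsError("spearman requires n >= 2")
    if not 0.0 < level < 1.0:
        raise StatsError("level must be in (0, 1)")
    rx, ry = midranks(x), midranks(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return SpearmanResult(math.nan, n, math.nan, math.nan, level, undefined=True)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if n > 3 and abs(r) < 1.0:
        lo, hi = fisher_ci(r, n, level)
    else:
        lo = hi = math.nan
    return SpearmanResult(r, n, lo, hi, level)


@dataclass(frozen=True)
class PassingBablokFit:
    """Passing–Bablok regression estimate with a slope confidence interval.

    ``n_slopes`` is N, the number of retained pairwise slopes (slopes exactly
    −1 discarded, identical points contributing nothing); ``k_offset`` is K,
    the number of slopes below −1, which shifts all median/CI indices.
    """

    slope: float
    intercept: float
    slope_ci_low: float
    slope_ci_high: float
    n_pairs: int
    n_slopes: int
    k_offset: int
    level: float = 0.95


def _order_stat(slopes: np.ndarray, rank_1based: int) -> float:
    """Order statistic with ranks clipped into [1, N]."""
    idx = min(max(rank_1based, 1), slopes.size) - 1
    return float(slopes[idx])


def passing_bablok(
    x: Sequence[float], y: Sequence[float], level: float = 0.95
) -> PassingBablokFit:
    """Fit the Passing–Bablok line y = a + b·x to paired measurements.

    All pairwise slopes S_ij with x_i ≠ x_j are formed; vertical pairs
    (x_i = x_j, y_i ≠ y_j) enter as ±∞ at the extremes of the ordered list;
    coincident points contribute nothing; slopes exactly equal to −1 are
    discarded.  With the ordered slopes S_(1) ≤ … ≤ S_(N) and K slopes < −1,
    the slope is the K-shifted median and its CI comes from the order
    statistics at M1 = ⌈(N − C)/2⌉ and M2 = N − M1 + 1 shifted by K, where
    C = z_{(1+level)/2}·√(n(n−1)(2n+5)/18).  The intercept is the median of
    y_i − b·x_i.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("x and y must be equal-length 1-d sequences")
    n = x.size
    if n < 3:
        raise StatsError("passing_bablok requires n >= 3")
    if np.all(x == x[0]):
        raise StatsError("all x identical: slope undefined")
    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(dx != 0.0, dy / np.where(dx == 0.0, 1.0, dx), np.sign(dy) * np.inf)
    keep = ~((dx == 0.0) & (dy == 0.0)) & (s != -1.0)
    slopes = np.sort(s[keep])
    n_slopes = int(slopes.size)
    if n_slopes == 0:
        raise StatsError("no usable pairwise slopes")
    k = int(np.sum(slopes < -1.0))
    if n_slopes % 2 == 1:
        b = _order_stat(slopes, (n_slopes + 1) // 2 + k)
    else:
        b = 0.5 * (
            _order_stat(slopes, n_slopes // 2 + k)
            + _order_stat(slopes, n_slopes // 2 + 1 + k)
        )
    z = norm.ppf((1.0 + level) / 2.0)
    c = z * math.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = math.ceil((n_slopes - c) / 2.0)
    m2 = n_slopes - m1 + 1
    lo = _order_stat(slopes, m1 + k)
    hi = _order_stat(slopes, m2 + k)
    a = float(np.median(y - b * x)) if math.isfinite(b) else math.nan
    return PassingBablokFit(b, a, lo, hi, n, n_slopes, k, level)


@dataclass(frozen=True)
class QuartileCrosstab:
    """Fractions of CFU results at or above each cutoff within one FBP quartile."""

    quartile: str
    n_in_quartile: int
    thresholds: tuple[int, ...]
    fractions: tuple[float, ...]

    def frac(self, threshold: int) -> float:
        """Fraction of the quartile's CFU values ≥ ``threshold``."""
        return self.fractions[self.thresholds.index(threshold)]

    @property
    def frac_cfu_ge5(self) -> float:
        return self.frac(5)

    @property
    def frac_cfu_ge10(self) -> float:
        return self.frac(10)


def quartile_crosstab(
    pairs: Sequence[PairedMeasurement],
    which: str = "lowest",
    thresholds: Sequence[int] = (5, 10),
) -> QuartileCrosstab:
    """Cross-tabulate CFU cutoffs within an FBP quartile.

    Pairs are stably sorted by FBP ≥3 µm (ties keep input order) and the
    lowest or highest ⌊n/4⌋ pairs are selected; for each cutoff the fraction
    of selected CFU values at or above it is reported.  All pairs must be
    non-excluded, and n ≥ 4 is required for a non-empty quartile.
    """
    if which not in {"lowest", "highest"}:
        raise StatsError(f"which must be 'lowest' or 'highest', got {which!r}")
    if any(p.excluded != EXCLUDE_NONE for p in pairs):
        raise StatsError("quartile_crosstab expects the non-excluded analysis pairs")
    n = len(pairs)
    if n < 4:
        raise StatsError("quartile_crosstab requires n >= 4")
    ordered = sorted(pairs, key=lambda p: p.fbp_ge3)  # stable
    m = n // 4
    selected = ordered[:m] if which == "lowest" else ordered[-m:]
    cfu = np.array([p.cfu_per_m3 for p in selected], dtype=float)
    fracs = tuple(float(np.mean(cfu >= t)) for t in thresholds)
    return QuartileCrosstab(which, m, tuple(int(t) for t in thresholds), fracs)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention used for reported values."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
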