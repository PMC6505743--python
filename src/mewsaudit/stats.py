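"""Descriptive and inferential statistics for the arm comparison.

Continuous summaries are medians with a single-number interquartile width
(Q3 − Q1); two-sample location shifts are tested with the Mann-Whitney
rank-sum test (tie-corrected normal approximation with continuity
correction, exact enumeration for small tie-free samples); 2×2 contingency
comparisons use Pearson's chi-square without continuity correction, falling
back to Fisher's exact test when any expected cell count is below 5. No
multiplicity correction is applied anywhere. Percentages are reported to one
decimal, rounded half-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "RankSumResult",
    "ContingencyResult",
    "median_iqr",
    "quartiles",
    "rank_sum_test",
    "contingency_test",
    "round_half_up",
    "percent",
]

QuartileRule = Literal["tukey", "exclusive", "linear"]


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal round-half-up (5 rounds away from zero), as clinical tables do."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage at table precision; raises on a zero denominator."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, decimals)


def quartiles(values: Sequence[float], rule: QuartileRule = "tukey") -> tuple[float, float]:
    """(Q1, Q3) under the chosen quartile rule.

    "tukey": hinges — each half includes the median when n is odd.
    "exclusive": Moore-McCabe — the median is excluded from both halves.
    "linear": NumPy's default linear interpolation of order statistics.
    The rule is configurable because published tables rarely say which one
    produced their IQRs.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("quartiles of empty sample")
    if rule == "linear":
        return float(np.percentile(x, 25)), float(np.percentile(x, 75))
    if rule == "tukey":
        half = (n + 1) // 2  # include median in both halves when n odd
        lower, upper = x[:half], x[n - half:]
    elif rule == "exclusive":
        half = n // 2
        lower, upper = x[:half], x[n - half:]
        if half == 0:  # n == 1
            lower = upper = x
    else:
        raise ValueError(f"unknown quartile rule {rule!r}")
    return float(np.median(lower)), float(np.median(upper))


def median_iqr(values: Sequence[float], rule: QuartileRule = "tukey") -> tuple[float, float]:
    """Median and interquartile *width* (Q3 − Q1)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("median_iqr of empty sample")
    q1, q3 = quartiles(x, rule)
    return float(np.median(x)), q3 - q1


# ---------------------------------------------------------------------------
# Mann-Whitney rank-sum test


@dataclass(frozen=True)
class RankSumResult:
    u_statistic: float  # U of the first sample
    z_score: float
    p_two_sided: float
    n_x: int
    n_y: int
    tie_correction_applied: bool
    exact: bool = False


#: largest min(n_x, n_y) for which the exact null distribution is enumerated
EXACT_MAX_MIN_N = 8


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Mann-Whitney U test for a location difference between two samples.

    U is computed from midranks. For small tie-free samples
    (min(n) ≤ 8) the two-sided p comes from exact enumeration of the null
    distribution of U (doubled lower tail, capped at 1); otherwise from the
    normal approximation with tie-corrected variance and a 0.5 continuity
    correction. Degenerate pooled data (every value identical) returns
    Z = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_x, n_y = x.size, y.size
    if n_x < 1 or n_y < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    r_x = float(ranks[:n_x].sum())
    u_x = r_x - n_x * (n_x + 1) / 2.0
    u_y = n_x * n_y - u_x

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    mu = n_x * n_y / 2.0
    n = n_x + n_y
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1)) if n > 1 else 0.0
    var = n_x * n_y / 12.0 * ((n + 1) - tie_term)

    if var <= 0:  # all pooled values identical
        return RankSumResult(u_x, 0.0, 1.0, n_x, n_y, has_ties, exact=False)

    if not has_ties and min(n_x, n_y) <= EXACT_MAX_MIN_N:
        p = _exact_two_sided_p(int(min(u_x, u_y)), n_x, n_y)
        # Z is still reported from the (uncorrected-tie) normal approximation
        z = _z_from_u(u_x, mu, var)
        return RankSumResult(u_x, z, p, n_x, n_y, False, exact=True)

    z = _z_from_u(u_x, mu, var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return RankSumResult(u_x, z, p, n_x, n_y, has_ties, exact=False)


def _z_from_u(u: float, mu: float, var: float) -> float:
    sd = math.sqrt(var)
    if u > mu:
        return (u - mu - 0.5) / sd
    if u < mu:
        return (u - mu + 0.5) / sd
    return 0.0


def _u_null_counts(m: int, n: int) -> np.ndarray:
    """counts[u] = number of the C(m+n, m) rank arrangements with U = u.

    Built from the Gaussian-binomial generating function
    prod_{j=1..m} (1 - q^{n+j}) / (1 - q^j), truncated at degree m*n.
    """
    size = m * n + 1
    poly = np.zeros(size, dtype=float)
    poly[0] = 1.0
    for j in range(1, m + 1):
        # multiply by (1 - q^(n+j))
        shifted = np.zeros_like(poly)
        if n + j < size:
            shifted[n + j:] = poly[: size - (n + j)]
        poly = poly - shifted
        # divide by (1 - q^j): cumulative sum with stride j
        for u in range(j, size):
            poly[u] += poly[u - j]
    return np.rint(poly)


def _exact_two_sided_p(u_min: int, n_x: int, n_y: int) -> float:
    m, n = min(n_x, n_y), max(n_x, n_y)
    counts = _u_null_counts(m, n)
    total = counts.sum()
    lower_tail = counts[: u_min + 1].sum() / total
    return min(1.0, 2.0 * lower_tail)


# ---------------------------------------------------------------------------
# 2x2 contingency tests


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    statistic: float  # chi-square statistic, or the Fisher odds ratio
    p_two_sided: float
    method: Literal["pearson_chi_square", "fisher_exact"]


def contingency_test(
    a: int,
    b: int,
    c: int,
    d: int,
    method: Literal["auto", "pearson_chi_square", "fisher_exact"] = "auto",
    fisher_mode: Literal["tail_summation", "doubling"] = "tail_summation",
) -> ContingencyResult:
    """Test of homogeneity on the 2×2 table [[a, b], [c, d]].

    Under ``method="auto"`` Pearson's chi-square (no continuity correction)
    is used unless any expected cell count is below 5, in which case
    Fisher's exact test is used. The two-sided Fisher p sums the
    probabilities of all tables at most as probable as the observed one
    (``tail_summation``, the conventional definition); ``doubling`` doubles
    the smaller hypergeometric tail instead.
    """
    for name, v in zip("abcd", (a, b, c, d)):
        if v < 0 or v != int(v):
            raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    table = np.array([[a, b], [c, d]], dtype=float)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("a row or column of the 2x2 table sums to zero; test undefined")
    expected = np.outer(row, col) / n

    if method == "auto":
        method = "fisher_exact" if np.any(expected < 5) else "pearson_chi_square"

    if method == "pearson_chi_square":
        stat, p, _, _ = sps.chi2_contingency(table, correction=False)
        return ContingencyResult(((a, b), (c, d)), float(stat), float(p), "pearson_chi_square")

    if fisher_mode == "tail_summation":
        odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    else:
        hg = sps.hypergeom(int(n), int(row[0]), int(col[0]))
        p = min(1.0, 2.0 * min(hg.cdf(a), hg.sf(a - 1)))
        odds = (a * d) / (b * c) if b * c > 0 else math.inf
    return ContingencyResult(((a, b), (c, d)), float(odds), float(p), "fisher_exact")
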