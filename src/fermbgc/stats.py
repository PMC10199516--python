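"""Statistical tests and summary-fraction arithmetic for the pipeline report.

The three tests used throughout the analysis — Pearson chi-squared
association, one-way ANOVA with Tukey HSD post hoc comparisons, and the
Wilcoxon rank-sum (Mann-Whitney) test — are computed from their textbook
definitions here; scipy supplies only the distribution tail functions
(chi-squared, F, studentized range, normal). The chi-squared statistic uses
no continuity correction, the Wilcoxon test is two-sided by default with an
exact enumeration for small tie-free samples, and percentages are rounded
half-up to two decimals to match the conventional printed style.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (so 0.005 -> 0.01, unlike banker's rounding)."""
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ChiSquaredResult:
    statistic: float
    df: int
    p: float
    expected: np.ndarray


def chi_squared(table) -> ChiSquaredResult:
    """Pearson chi-squared test of association on an r x c contingency table.

    statistic = sum (O - E)^2 / E with E from the row/column margins; no
    continuity correction; df = (r - 1)(c - 1). Raises if any margin is zero
    (expected cell would be zero).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2 x 2")
    if (obs < 0).any():
        raise ValueError("contingency table cells must be non-negative")
    total = obs.sum()
    if total <= 0:
        raise ValueError("contingency table grand total must be positive")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    for i, r in enumerate(row):
        if r == 0:
            raise ValueError(f"row margin {i} is zero: expected cells undefined")
    for j, c in enumerate(col):
        if c == 0:
            raise ValueError(f"column margin {j} is zero: expected cells undefined")
    expected = np.outer(row, col) / total
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(statistic, df))
    return ChiSquaredResult(statistic, df, p, expected)


@dataclass
class TukeyComparison:
    group_a: str
    group_b: str
    difference: float  # mean_b - mean_a
    p_adjusted: float


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    tukey: list[TukeyComparison]


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way ANOVA F test plus Tukey HSD pairwise comparisons.

    F = MS_between / MS_within on the usual sum-of-squares decomposition;
    each Tukey pair reports the mean difference and an adjusted p from the
    studentized-range distribution at the pooled within-group variance
    (Tukey-Kramer scaling for unequal group sizes).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in data.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 values")
    n_total = sum(v.size for v in data.values())
    grand = sum(v.sum() for v in data.values()) / n_total
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in data.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    df_between = len(names) - 1
    df_within = n_total - len(names)
    if ss_within <= 0:
        raise ValueError("zero within-group variance: F statistic degenerate")
    ms_within = ss_within / df_within
    F = (ss_between / df_between) / ms_within
    p = float(sps.f.sf(F, df_between, df_within))

    k = len(names)
    tukey: list[TukeyComparison] = []
    for a, b in combinations(names, 2):
        va, vb = data[a], data[b]
        diff = vb.mean() - va.mean()
        se = math.sqrt(ms_within / 2.0 * (1.0 / va.size + 1.0 / vb.size))
        q = abs(diff) / se
        p_adj = float(sps.studentized_range.sf(q, k, df_within))
        tukey.append(TukeyComparison(a, b, float(diff), min(1.0, p_adj)))
    return AnovaResult(float(F), df_between, df_within, p, tukey)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank sum of x, p).

    Ties receive average ranks. The p-value is exact by enumeration of rank
    assignments when n_x + n_y <= 12 and there are no ties, otherwise a
    normal approximation with tie correction and a continuity correction is
    used (matching R's wilcox.test default).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:nx].sum())
    mu = nx * (n + 1) / 2.0
    has_ties = len(np.unique(pooled)) < n

    if n <= 12 and not has_ties:
        # exact: enumerate all C(n, nx) assignments of ranks to the x sample
        dev = abs(w - mu)
        count = 0
        total = 0
        for combo in combinations(range(1, n + 1), nx):
            total += 1
            if abs(sum(combo) - mu) >= dev - 1e-12:
                count += 1
        return w, count / total

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 1.0  # all observations tied
    z = max(0.0, abs(w - mu) - 0.5) / math.sqrt(var)
    return w, min(1.0, 2.0 * float(sps.norm.sf(z)))


@dataclass(frozen=True)
class FractionEntry:
    label: str
    numerator: int
    denominator: int
    percent: float | None  # None when the denominator is zero

    def __str__(self) -> str:
        pct = "undefined" if self.percent is None else f"{self.percent:.2f}%"
        return f"{self.label}: {self.numerator}/{self.denominator} = {pct}"


def summary_fractions(
    counts: Sequence[tuple[str, int, int]]
) -> list[FractionEntry]:
    """Turn (label, numerator, denominator) counts into 2-decimal percentages.

    Pure arithmetic: a zero denominator yields an entry marked undefined
    rather than being dropped.
    """
    out: list[FractionEntry] = []
    for label, num, den in counts:
        if num < 0 or den < 0 or num > den:
            raise ValueError(f"{label}: need 0 <= numerator <= denominator, got {num}/{den}")
        pct = round_half_up(100.0 * num / den, 2) if den else None
        out.append(FractionEntry(label, num, den, pct))
    return out
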