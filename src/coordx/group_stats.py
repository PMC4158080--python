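"""Nonparametric statistical layer for skewed gene-feature distributions.

Group comparisons use rank-based tests throughout — Mann-Whitney U for two
samples, Kruskal-Wallis H for more — because gene lengths, expression
levels and densities are strongly right-skewed.  Prevalence contrasts use
the Pearson chi-square without continuity correction; monotone association
is measured by Spearman's rank correlation.  All p-values are two-sided.

The boxplot summary follows the figure convention used for these data:
box at the 25/50/75th percentiles, whiskers at the 12.5th and 87.5th,
all computed by linear interpolation between order statistics (the
"type 7" rule), so each whisker spans a further 12.5% of the population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "BoxplotSummary",
    "SpearmanResult",
    "mann_whitney_u",
    "kruskal_wallis",
    "chi_square_prevalence",
    "spearman",
    "boxplot_summary",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test.

    ``effect_direction`` is the sign of ``median(x) - median(y)`` for
    two-group tests (+1, -1 or 0) and ``None`` otherwise.
    """

    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    effect_direction: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if any(n < 1 for n in self.n_per_group):
            raise ValueError("all group sizes must be >= 1")


@dataclass(frozen=True)
class BoxplotSummary:
    """Five-number summary with whiskers at the 12.5/87.5th percentiles."""

    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    n: int

    def __post_init__(self) -> None:
        if not (self.whisker_low <= self.q25 <= self.median <= self.q75 <= self.whisker_high):
            raise ValueError("boxplot summary out of order")


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    constant_input: bool = False


def _direction(x: np.ndarray, y: np.ndarray) -> int:
    d = float(np.median(x) - np.median(y))
    return 0 if d == 0 else (1 if d > 0 else -1)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], method: str = "asymptotic"
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    The statistic is U for the first sample with midrank tie handling.
    ``method="asymptotic"`` (default) uses the normal approximation with
    tie-corrected variance and continuity correction; ``"exact"`` uses full
    enumeration (tie-free samples only, small n); ``"auto"`` lets scipy
    choose.  Degenerate case: when every pooled value is identical the
    test carries no information and (U = n1*n2/2, p = 1) is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.all(x == x.flat[0]) and np.all(y == x.flat[0]):
        return TestResult("mann_whitney_u", x.size * y.size / 2.0, 1.0, (x.size, y.size), 0)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    return TestResult("mann_whitney_u", float(res.statistic), p, (x.size, y.size), _direction(x, y))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test with tie correction; p from chi-square(k-1).

    Accepts two or more groups (typical use is three or more).  If every
    pooled value is identical, H = 0 and p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return TestResult("kruskal_wallis", 0.0, 1.0, tuple(a.size for a in arrs))
    res = stats.kruskal(*arrs)
    return TestResult(
        "kruskal_wallis", float(res.statistic), float(res.pvalue), tuple(a.size for a in arrs)
    )


def chi_square_prevalence(table: Sequence[Sequence[float]]) -> TestResult:
    """Pearson chi-square on an r x c contingency table, no continuity
    correction, df = (r-1)(c-1).

    Requires at least a 2x2 table and strictly positive marginals (so all
    expected counts are positive).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError(f"need at least a 2x2 table, got shape {t.shape}")
    if np.any(t < 0):
        raise ValueError("negative counts in contingency table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table: expected counts undefined")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=False)
    return TestResult("chi_square", float(chi2), float(p), tuple(int(r) for r in t.sum(axis=1)))


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation (Pearson on midranks), two-sided p via the
    t approximation.  A constant input vector leaves rho undefined; the
    result is flagged instead of raising."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(float("nan"), float("nan"), int(x.size), constant_input=True)
    rho, p = stats.spearmanr(x, y)
    return SpearmanResult(float(rho), float(p), int(x.size))


def boxplot_summary(values: Sequence[float]) -> BoxplotSummary:
    """Empirical 12.5/25/50/75/87.5th percentiles by linear interpolation."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    wl, q25, med, q75, wh = np.percentile(v, [12.5, 25, 50, 75, 87.5], method="linear")
    return BoxplotSummary(float(med), float(q25), float(q75), float(wl), float(wh), int(v.size))
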