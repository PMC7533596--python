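"""Group-comparison statistics for behavioral and kinematic measures.

Behavioral scores (open field, neurological examinations) are compared
with rank-based tests: Kruskal-Wallis across groups and Wilcoxon
(rank-sum for independent groups, signed-rank for paired) pairwise.
Kinematic measures (step speeds, curve-distance summaries) use multiple
Welch t-tests with Bonferroni correction across the family of
comparisons.  Significance threshold throughout: p < 0.05 (on the
adjusted p where a correction applies).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupSample",
    "TestResult",
    "kruskal_wallis",
    "wilcoxon_pairwise",
    "multiple_t_bonferroni",
]

#: above this combined sample size, rank tests switch from exact enumeration
#: to the tie-corrected large-sample approximation
EXACT_RANK_LIMIT = 25


@dataclass(frozen=True)
class GroupSample:
    """Measurements for one group: one value per mouse (or per step)."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or len(vals) < 2:
            raise ValueError(f"group {self.label!r} needs >= 2 values")
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"group {self.label!r} has non-finite values")
        vals = vals.copy()
        vals.flags.writeable = False
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_raw: float
    p_adjusted: float
    comparison: tuple[str, ...]
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_raw <= 1.0:
            raise ValueError("p_raw outside [0, 1]")
        if self.p_adjusted < self.p_raw - 1e-15 or self.p_adjusted > 1.0:
            raise ValueError("p_adjusted must satisfy p_raw <= p_adjusted <= 1")


def kruskal_wallis(samples: Sequence[GroupSample]) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected) across >= 2 groups.

    When every observation is identical the tie correction degenerates;
    by convention H = 0 and p = 1 (no evidence of any group difference).
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    labels = [s.label for s in samples]
    if len(set(labels)) != len(labels):
        raise ValueError("group labels must be unique")
    pooled = np.concatenate([s.values for s in samples])
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, 1.0, tuple(labels), "kruskal-wallis")
    h, p = stats.kruskal(*[s.values for s in samples])
    return TestResult(float(h), float(p), float(p), tuple(labels), "kruskal-wallis")


def wilcoxon_pairwise(
    a: GroupSample, b: GroupSample, *, paired: bool = False,
    alternative: str = "two-sided",
) -> TestResult:
    """Wilcoxon two-group comparison: rank-sum (unpaired) or signed-rank (paired).

    Exact enumeration is used for small samples (combined n <= 25 and no
    ties for the signed-rank); above that, the tie-corrected normal
    approximation.
    """
    if paired:
        if a.n != b.n:
            raise ValueError("paired test requires equal sample sizes")
        diffs = a.values - b.values
        if np.all(diffs == 0):
            raise ValueError(
                "all paired differences are zero; signed-rank test undefined"
            )
        mode = "exact" if a.n <= EXACT_RANK_LIMIT and len(
            np.unique(np.abs(diffs[diffs != 0]))
        ) == np.count_nonzero(diffs) else "approx"
        stat, p = stats.wilcoxon(
            a.values, b.values, mode=mode, alternative=alternative
        )
        method = "wilcoxon-signed-rank"
    else:
        mode = "exact" if a.n + b.n <= EXACT_RANK_LIMIT else "asymptotic"
        try:
            res = stats.mannwhitneyu(
                a.values, b.values, method=mode, alternative=alternative
            )
        except ValueError:
            # ties make the exact distribution unavailable; fall back
            res = stats.mannwhitneyu(
                a.values, b.values, method="asymptotic", alternative=alternative
            )
        stat, p = res.statistic, res.pvalue
        method = "wilcoxon-rank-sum"
    return TestResult(
        float(stat), float(p), float(p), (a.label, b.label), method
    )


def multiple_t_bonferroni(
    comparisons: Sequence[tuple[GroupSample, GroupSample]],
    *,
    equal_var: bool = False,
) -> list[TestResult]:
    """Two-sided t-tests over a family of comparisons, Bonferroni-adjusted.

    Welch's unequal-variance t by default (``equal_var=True`` switches to
    the pooled-variance form).  Adjusted p is ``min(1, m * p_raw)`` with m
    the number of comparisons in the family.
    """
    m = len(comparisons)
    if m == 0:
        raise ValueError("no comparisons given")
    out = []
    for a, b in comparisons:
        if np.var(a.values) == 0 and np.var(b.values) == 0:
            raise ValueError(
                f"zero variance in both groups ({a.label!r}, {b.label!r}); "
                "t-test undefined"
            )
        t, p = stats.ttest_ind(a.values, b.values, equal_var=equal_var)
        out.append(
            TestResult(
                float(t), float(p), min(1.0, m * float(p)),
                (a.label, b.label),
                "welch-t" if not equal_var else "pooled-t",
            )
        )
    return out
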