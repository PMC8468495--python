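"""Statistical significance for rate-disparity results.

Whether a subgroup's rate differs between the real and synthetic table is
tested with a pooled two-proportion z-test,

    z = (p_S - p_R) / sqrt( p(1-p)/n_S + p(1-p)/n_R ),
    p = (count_S + count_R) / (n_S + n_R),

falling back to Fisher's exact test when any expected cell count of the 2x2
(in/out of subgroup x real/synthetic) table under the pooled proportion is
below a threshold (default 5, the textbook rule). Because many subgroups are
tested per run, p-values are adjusted once per run with Benjamini–Hochberg
to control the false discovery rate; "significant" always refers to the
adjusted p-value at level alpha (default 0.05). Tests are two-sided: over-
and under-representation are equally interesting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateTestError


@dataclass(frozen=True)
class TestResult:
    """Outcome of one two-sample proportion test.

    ``statistic`` is the z value for the z-test and None for the exact test.
    ``p_adjusted``/``significant`` are filled in after the per-run
    Benjamini–Hochberg pass; until then they equal the raw p-value /
    raw-level decision.
    """

    statistic: Optional[float]
    p_value: float
    method: str  # "z_test" | "fisher_exact"
    p_adjusted: float
    significant: bool
    alpha: float = 0.05

    def with_adjustment(self, p_adjusted: float, alpha: float = 0.05) -> "TestResult":
        return replace(self, p_adjusted=p_adjusted, significant=p_adjusted < alpha, alpha=alpha)


def two_proportion_z(count_S: int, n_S: int, count_R: int, n_R: int) -> TestResult:
    """Pooled two-proportion z-test of p_S = p_R (two-sided).

    Degenerate pooled proportions (0 or 1) mean both samples agree exactly on
    an all-or-nothing rate: p_value 1.0 is returned when p_S == p_R, and a
    :class:`DegenerateTestError` is raised otherwise (cannot happen for
    counts within range, kept as a guard).
    """
    if n_S < 1 or n_R < 1:
        raise ValueError("sample sizes must be >= 1")
    p_S = count_S / n_S
    p_R = count_R / n_R
    pooled = (count_S + count_R) / (n_S + n_R)
    if pooled in (0.0, 1.0):
        if p_S == p_R:
            return TestResult(0.0, 1.0, "z_test", 1.0, False)
        raise DegenerateTestError("pooled proportion is 0 or 1 with unequal sample proportions")
    se = math.sqrt(pooled * (1 - pooled) * (1 / n_S + 1 / n_R))
    z = (p_S - p_R) / se
    p_value = 2 * stats.norm.sf(abs(z))
    return TestResult(z, float(p_value), "z_test", float(p_value), p_value < 0.05)


def fisher_exact(count_S: int, n_S: int, count_R: int, n_R: int) -> TestResult:
    """Two-sided Fisher exact test on the 2x2 in/out x synthetic/real table.

    The two-sided p-value sums the hypergeometric probabilities of all
    tables (with the observed margins) at most as probable as the observed
    one. Degenerate tables give p = 1.
    """
    table = [[count_S, n_S - count_S], [count_R, n_R - count_R]]
    _, p_value = stats.fisher_exact(table, alternative="two-sided")
    return TestResult(None, float(p_value), "fisher_exact", float(p_value), p_value < 0.05)


def subgroup_rate_test(
    count_S: int,
    n_S: int,
    count_R: int,
    n_R: int,
    expected_cell_min: float = 5.0,
) -> TestResult:
    """z-test, or Fisher fallback when any pooled expected cell count is small."""
    pooled = (count_S + count_R) / (n_S + n_R)
    expected = (n_S * pooled, n_S * (1 - pooled), n_R * pooled, n_R * (1 - pooled))
    if min(expected) < expected_cell_min:
        return fisher_exact(count_S, n_S, count_R, n_R)
    return two_proportion_z(count_S, n_S, count_R, n_R)


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    Sort ascending, scale p_(i) by m/i, enforce monotonicity from the
    largest rank down, cap at 1.
    """
    if len(p_values) == 0:
        raise ValueError("p_values must be non-empty")
    for p in p_values:
        if not (0 <= p <= 1):
            raise ValueError(f"p-value outside [0, 1]: {p}")
    _, adjusted, _, _ = multipletests(list(p_values), method="fdr_bh")
    return [float(p) for p in adjusted]
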