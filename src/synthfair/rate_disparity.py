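"""Log disparity on subgroup representation rates.

The core metric compares how often a protected subgroup occurs in the
synthetic data versus the real data it was generated from. With
p_S = P(g(x)=1 | x in S) and p_R = P(g(x)=1 | x in R), and
odds(p) = p / (1 - p), the log disparity is

    LD = ln( odds(p_S) / odds(p_R) )

LD = 0 means parity; positive LD means the subgroup is over-represented in
the synthetic data. This is the synthetic-data analogue of the ML-fairness
disparate impact ratio: for real/synthetic sampling indicators that are
independent of each other and of group membership, the disparate impact
ratio P(y'=1|g=1)/P(y'=1|g=0) reduces exactly to odds(p_S)/odds(p_R)
(see :func:`disparate_impact_oracle`, which checks this identity by brute
force on finite populations).

Values are bucketed into six representativeness categories using the 90%
and 80% rules: |LD| < |ln 0.9| is adequate; up to |ln 0.8| is over/under;
beyond that highly over/under; a subgroup present in real data but absent
from synthetic data is "missing" (the mode-collapse signal).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import DatasetPair
from .errors import (
    DegeneratePopulationError,
    DegenerateSubgroupError,
    ReferenceGroupError,
)
from .significance import TestResult, benjamini_hochberg, subgroup_rate_test
from .subgroups import SubgroupDefinition, enumerate_subgroups, membership_counts

#: Sentinel returned by :func:`log_disparity` when the subgroup is missing
#: from the synthetic data (count_S = 0). Kept as None so it survives JSON
#: and CSV round-trips unambiguously (NaN would be indistinguishable from a
#: computation failure).
MISSING = None


class CategoryLevel(str, enum.Enum):
    """Six-level representativeness scale."""

    HIGHLY_OVER = "highly_over"
    OVER = "over"
    ADEQUATE = "adequate"
    UNDER = "under"
    HIGHLY_UNDER = "highly_under"
    MISSING = "missing"


#: Report palette. Only "missing = red" is semantically fixed; the rest is a
#: documented choice (diverging teal/orange).
CATEGORY_COLORS: dict[CategoryLevel, str] = {
    CategoryLevel.HIGHLY_OVER: "#b35806",
    CategoryLevel.OVER: "#fdb863",
    CategoryLevel.ADEQUATE: "#1b9e8f",
    CategoryLevel.UNDER: "#b2abd2",
    CategoryLevel.HIGHLY_UNDER: "#542788",
    CategoryLevel.MISSING: "#d7191c",
}


@dataclass(frozen=True)
class CategoryScale:
    """Thresholds of the 90%/80% rules on the log scale.

    t1 = |ln 0.9| separates adequate from over/under; t2 = |ln 0.8| separates
    over/under from highly over/under. Ties go to the more severe side.
    """

    t1: float = abs(math.log(0.9))
    t2: float = abs(math.log(0.8))

    def __post_init__(self):
        if not (0 < self.t1 < self.t2):
            raise ValueError("category scale requires 0 < t1 < t2")


DEFAULT_SCALE = CategoryScale()


def odds(p: float) -> float:
    """odds(p) = p / (1 - p) for 0 <= p < 1; odds(0) = 0."""
    if not 0 <= p < 1:
        if p == 1:
            raise DegenerateSubgroupError("p = 1: subgroup is the entire dataset, odds undefined")
        raise ValueError(f"proportion must lie in [0, 1), got {p}")
    return p / (1.0 - p)


def log_disparity(
    count_S: int,
    n_S: int,
    count_R: int,
    n_R: int,
    continuity_correction: bool = False,
) -> Optional[float]:
    """ln(odds_S / odds_R) from subgroup counts; None if missing in synthetic.

    Parameters
    ----------
    count_S, n_S
        Subgroup count and total rows in the synthetic data.
    count_R, n_R
        Same in the real data; ``count_R`` must be >= 1 (a subgroup absent
        from the real data has no reference rate and is not evaluable).
    continuity_correction
        Add the Haldane–Anscombe 0.5 to all four cells of the implied 2x2
        table. Off by default; useful for sparse tables where a single-count
        subgroup otherwise produces extreme log odds.

    Returns
    -------
    float or None
        The log disparity, or the ``MISSING`` sentinel (None) when
        ``count_S == 0``: the subgroup exists in real data but vanished from
        the synthetic data (mode collapse). The missing sentinel takes
        precedence over the continuity correction.
    """
    if n_S < 1 or n_R < 1:
        raise ValueError("dataset sizes must be >= 1")
    if not (0 <= count_S <= n_S and 0 <= count_R <= n_R):
        raise ValueError("counts must satisfy 0 <= count <= n")
    if count_R == 0:
        raise ReferenceGroupError("subgroup absent from real data: disparity not evaluable")
    if count_R == n_R or count_S == n_S:
        raise DegenerateSubgroupError("subgroup covers an entire dataset: odds undefined")
    if count_S == 0:
        return MISSING
    if continuity_correction:
        a, b = count_S + 0.5, (n_S - count_S) + 0.5
        c, d = count_R + 0.5, (n_R - count_R) + 0.5
        return math.log((a / b) / (c / d))
    odds_S = count_S / (n_S - count_S)
    odds_R = count_R / (n_R - count_R)
    return math.log(odds_S / odds_R)


def categorize(ld: Optional[float], scale: CategoryScale = DEFAULT_SCALE) -> CategoryLevel:
    """Map a log disparity (or the missing sentinel) to the six-level scale."""
    if ld is MISSING:
        return CategoryLevel.MISSING
    mag = abs(ld)
    if mag < scale.t1:
        return CategoryLevel.ADEQUATE
    if mag < scale.t2:
        return CategoryLevel.OVER if ld > 0 else CategoryLevel.UNDER
    return CategoryLevel.HIGHLY_OVER if ld > 0 else CategoryLevel.HIGHLY_UNDER


@dataclass
class RateDisparityResult:
    """Counts, proportions, disparity, category and test for one subgroup."""

    subgroup: SubgroupDefinition
    count_R: int
    count_S: int
    n_R: int
    n_S: int
    log_disparity: Optional[float]
    category: CategoryLevel
    test: Optional[TestResult] = None
    flags: tuple[str, ...] = ()

    @property
    def p_R(self) -> float:
        return self.count_R / self.n_R

    @property
    def p_S(self) -> float:
        return self.count_S / self.n_S

    @property
    def odds_R(self) -> float:
        return odds(self.p_R)

    @property
    def odds_S(self) -> float:
        return odds(self.p_S)

    @property
    def disparity_ratio(self) -> Optional[float]:
        if self.log_disparity is MISSING:
            return 0.0 if self.count_S == 0 else None
        return math.exp(self.log_disparity)

    @property
    def significant(self) -> Optional[bool]:
        return None if self.test is None else self.test.significant


def evaluate_rates(
    pair: DatasetPair,
    subgroups: Optional[list[SubgroupDefinition]] = None,
    max_order: int | str = "all",
    scale: CategoryScale = DEFAULT_SCALE,
    alpha: float = 0.05,
    continuity_correction: bool = False,
    expected_cell_min: float = 5.0,
) -> list[RateDisparityResult]:
    """Rate disparity + significance for every evaluable subgroup of a pair.

    Subgroups default to the full enumeration up to ``max_order``. Subgroups
    with ``count_R == 0`` (no real reference) or covering an entire table are
    skipped — they are structurally not evaluable, unlike "missing" subgroups
    (present in real, absent in synthetic), which are reported with the
    missing category. Benjamini–Hochberg is applied once across all tested
    subgroups; ``significant`` means adjusted p < alpha.
    """
    if subgroups is None:
        subgroups = enumerate_subgroups(pair.schema, max_order=max_order)
    n_R, n_S = pair.real.n, pair.synthetic.n

    kept: list[tuple[SubgroupDefinition, int, int, Optional[float]]] = []
    for sg in subgroups:
        count_R, _ = membership_counts(pair.real, sg)
        count_S, _ = membership_counts(pair.synthetic, sg)
        try:
            ld = log_disparity(count_S, n_S, count_R, n_R, continuity_correction)
        except (ReferenceGroupError, DegenerateSubgroupError):
            continue
        kept.append((sg, count_R, count_S, ld))

    tests = [
        subgroup_rate_test(count_S, n_S, count_R, n_R, expected_cell_min=expected_cell_min)
        for _, count_R, count_S, _ in kept
    ]
    adjusted = benjamini_hochberg([t.p_value for t in tests]) if tests else []
    results: list[RateDisparityResult] = []
    for (sg, count_R, count_S, ld), test, p_adj in zip(kept, tests, adjusted):
        test = test.with_adjustment(p_adj, alpha=alpha)
        results.append(
            RateDisparityResult(
                subgroup=sg,
                count_R=count_R,
                count_S=count_S,
                n_R=n_R,
                n_S=n_S,
                log_disparity=ld,
                category=categorize(ld, scale),
                test=test,
                flags=("missing_in_synthetic",) if ld is MISSING else (),
            )
        )
    return results


RESULT_COLUMNS = (
    "subgroup", "order", "count_real", "count_synthetic", "n_real", "n_synthetic",
    "p_real", "p_synthetic", "log_disparity", "disparity_ratio", "category",
    "color", "test_method", "z", "p_value", "p_adjusted", "significant",
    "starred", "flags",
)


def results_to_frame(results: list[RateDisparityResult]) -> pd.DataFrame:
    """Flatten results to the report table layout (one row per subgroup)."""
    rows = []
    for r in results:
        rows.append(
            {
                "subgroup": r.subgroup.label(),
                "order": r.subgroup.order,
                "count_real": r.count_R,
                "count_synthetic": r.count_S,
                "n_real": r.n_R,
                "n_synthetic": r.n_S,
                "p_real": r.p_R,
                "p_synthetic": r.p_S,
                "log_disparity": np.nan if r.log_disparity is MISSING else r.log_disparity,
                "disparity_ratio": np.nan if r.disparity_ratio is None else r.disparity_ratio,
                "category": r.category.value,
                "color": CATEGORY_COLORS[r.category],
                "test_method": r.test.method if r.test else "",
                "z": np.nan if r.test is None or r.test.statistic is None else r.test.statistic,
                "p_value": np.nan if r.test is None else r.test.p_value,
                "p_adjusted": np.nan if r.test is None else r.test.p_adjusted,
                "significant": bool(r.significant) if r.significant is not None else False,
                "starred": (not r.significant) if r.significant is not None else True,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def disparate_impact_oracle(population: pd.DataFrame) -> tuple[float, float]:
    """Brute-force check that disparate impact equals the odds ratio.

    ``population`` is a finite table with binary columns ``g`` (subgroup
    membership), ``y`` (sampled into the real data) and ``yprime`` (sampled
    into the synthetic data), constructed so that y is independent of yprime
    and of g. Returns

    - the disparate impact ratio P(y'=1 | g=1) / P(y'=1 | g=0), computed by
      direct frequency counting, and
    - odds(P(g=1 | y'=1)) / odds(P(g=1 | y=1)), the odds-ratio form
      estimable from actual real/synthetic tables.

    Under the independence assumptions the two agree to machine precision.
    """
    for col in ("g", "y", "yprime"):
        if col not in population.columns:
            raise ValueError(f"population table must have column {col!r}")
    g = population["g"].to_numpy().astype(bool)
    yp = population["yprime"].to_numpy().astype(bool)
    y = population["y"].to_numpy().astype(bool)

    n_g1, n_g0 = g.sum(), (~g).sum()
    if n_g1 == 0 or n_g0 == 0:
        raise DegeneratePopulationError("population must contain both g=1 and g=0 subjects")
    p_yp_g1 = (yp & g).sum() / n_g1
    p_yp_g0 = (yp & ~g).sum() / n_g0
    if p_yp_g0 == 0 or p_yp_g1 == 0:
        raise DegeneratePopulationError("zero synthetic-sampling frequency in a group")
    eq_di = p_yp_g1 / p_yp_g0

    n_yp, n_y = yp.sum(), y.sum()
    if n_yp == 0 or n_y == 0:
        raise DegeneratePopulationError("population must contain sampled rows for both tables")
    p_g_S = (g & yp).sum() / n_yp
    p_g_R = (g & y).sum() / n_y
    if not (0 < p_g_S < 1 and 0 < p_g_R < 1):
        raise DegeneratePopulationError("degenerate subgroup frequency among sampled rows")
    odds_ratio = odds(p_g_S) / odds(p_g_R)
    return float(eq_di), float(odds_ratio)
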