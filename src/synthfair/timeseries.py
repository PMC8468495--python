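"""Time-series log disparity: fairness of temporal resemblance.

For longitudinal data, rate parity alone misses whether the synthetic data
track a subgroup's temporal *trends*. Each subgroup's rows are collapsed,
per temporal feature, into one length-T series with an aggregation statistic
f (mean by default; count/sum for event-count data), separately in the real
and synthetic tables. A resemblance statistic res(TS_r, TS_s) then scores
how well the synthetic series tracks the real one:

- mapped Pearson correlation, (r + 1) / 2 in [0, 1];
- directional symmetry (DS), the percentage of consecutive steps where the
  two series move in the same direction (ties count as agreement).

The time-series log disparity contrasts the subgroup with its complement
(all remaining rows of the same table):

    TS-LD = ln( res(subgroup) / res(complement) )

and is bucketed with the same six-level 90%/80% scale as rate disparity.
PCC and DS probe different failure modes — location/scale-free linear
correlation vs step-direction concordance — and can disagree in category on
the same data; both are therefore reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data_model import DatasetPair, TabularDataset
from .errors import EmptySubgroupError, UndefinedResemblanceError
from .rate_disparity import DEFAULT_SCALE, CategoryLevel, CategoryScale, categorize
from .subgroups import SubgroupDefinition

CONCATENATED = "concatenated"


@dataclass
class SeriesPair:
    """Aggregated real (a) and synthetic (b) series for one subgroup/feature."""

    subgroup: SubgroupDefinition
    feature: str
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1 or len(self.a) < 2:
            raise ValueError("series must be 1-D, equal length, N >= 2")
        if not (np.isfinite(self.a).all() and np.isfinite(self.b).all()):
            raise ValueError("series values must be finite")


@dataclass
class TimeSeriesDisparityResult:
    """Subgroup-vs-complement resemblance and its log disparity."""

    subgroup: SubgroupDefinition
    metric: str  # "pcc" | "ds"
    res_g1: Optional[float]
    res_g0: Optional[float]
    ts_log_disparity: Optional[float]
    category: Optional[CategoryLevel]
    per_feature: Optional[dict[str, tuple[Optional[float], Optional[float], Optional[float]]]] = None
    flags: tuple[str, ...] = ()


def aggregate_series(
    dataset: TabularDataset,
    subgroup: SubgroupDefinition,
    statistic: Optional[str] = None,
    complement: bool = False,
) -> dict[str, np.ndarray]:
    """Collapse a subgroup's rows into one length-T series per feature.

    ``statistic`` defaults to the schema's aggregation statistic. "mean" and
    "sum" are arithmetic over the subgroup's rows per time column; "count"
    counts rows with a nonzero value at that column (the natural reading for
    binary diagnosis indicators). With ``complement=True`` the rows with
    g(x)=0 are aggregated instead.
    """
    schema = dataset.schema
    if not schema.temporal_features:
        raise ValueError("schema declares no temporal features")
    statistic = statistic or schema.aggregation_statistic
    mask = subgroup.matches(dataset.records)
    if complement:
        mask = ~mask
    if not mask.any():
        raise EmptySubgroupError(
            f"no rows match {'complement of ' if complement else ''}{subgroup.label()}"
        )
    rows = dataset.records.loc[mask]
    out: dict[str, np.ndarray] = {}
    for feature, cols in schema.temporal_features:
        block = rows[list(cols)].to_numpy(dtype=float)
        if statistic == "mean":
            series = block.mean(axis=0)
        elif statistic == "sum":
            series = block.sum(axis=0)
        elif statistic == "count":
            series = (block != 0).sum(axis=0).astype(float)
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
        out[feature] = series
    return out


def pcc_mapped(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation mapped from [-1, 1] to [0, 1]: (r + 1) / 2.

    Population moments are used in both numerator and denominator (the
    normalisation cancels in r). Constant series have no defined
    correlation and raise :class:`UndefinedResemblanceError` with reason
    ``zero_variance_real`` / ``zero_variance_synthetic``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("series must be 1-D, equal length, N >= 2")
    if np.ptp(a) == 0:
        raise UndefinedResemblanceError("zero_variance_real", "real series is constant")
    if np.ptp(b) == 0:
        raise UndefinedResemblanceError("zero_variance_synthetic", "synthetic series is constant")
    r = float(np.corrcoef(a, b)[0, 1])
    return (r + 1.0) / 2.0


def directional_symmetry(a: np.ndarray, b: np.ndarray) -> float:
    """Percentage of steps where a and b move in the same direction.

    DS = 100/(N-1) * sum_k d_k with d_k = 1 iff
    (a_{k+1} - a_k)(b_{k+1} - b_k) >= 0 — a zero step in either series
    counts as agreement.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("series must be 1-D, equal length, N >= 2")
    agree = (np.diff(a) * np.diff(b)) >= 0
    return 100.0 * float(agree.sum()) / (len(a) - 1)


def resemblance(a: np.ndarray, b: np.ndarray, metric: str) -> float:
    if metric == "pcc":
        return pcc_mapped(a, b)
    if metric == "ds":
        return directional_symmetry(a, b)
    raise ValueError(f"unknown resemblance metric {metric!r} (expected 'pcc' or 'ds')")


def ts_log_disparity(res_g1: float, res_g0: float) -> float:
    """ln(res_g1 / res_g0); both resemblances must be positive and on one scale.

    Any common scale factor (DS's x100, the PCC mapping's /2) cancels in the
    ratio. A zero resemblance makes the ratio undefined and raises; batch
    evaluation converts that into a flagged worst-category row.
    """
    if res_g1 < 0 or res_g0 < 0:
        raise ValueError("resemblance values must be non-negative")
    if res_g1 == 0:
        raise UndefinedResemblanceError("zero_resemblance_subgroup")
    if res_g0 == 0:
        raise UndefinedResemblanceError("zero_resemblance_complement")
    return math.log(res_g1 / res_g0)


def _series_missing(dataset: TabularDataset, subgroup: SubgroupDefinition) -> bool:
    return not subgroup.matches(dataset.records).any()


def _safe_res(a: np.ndarray, b: np.ndarray, metric: str) -> tuple[Optional[float], Optional[str]]:
    try:
        return resemblance(a, b, metric), None
    except UndefinedResemblanceError as exc:
        return None, exc.reason


def evaluate_timeseries(
    pair: DatasetPair,
    subgroups: list[SubgroupDefinition],
    metric: str = "pcc",
    statistic: Optional[str] = None,
    mode: str = "per_feature",
    scale: CategoryScale = DEFAULT_SCALE,
) -> list[TimeSeriesDisparityResult]:
    """Time-series log disparity for each subgroup of a pair.

    For every subgroup, the subgroup's and its complement's aggregated
    series are built in both tables and scored with ``metric``. In
    ``per_feature`` mode each feature is scored separately and the summary
    resemblance is the arithmetic mean over features (the expectation over
    the subgroup's series); in ``concatenated`` mode the features are joined
    in schema order into one series of length m*T before scoring.

    A subgroup present in real data but absent from synthetic data is
    reported as category missing. Undefined resemblances (constant series,
    zero resemblance) become flagged rows; the run never aborts on one
    subgroup.
    """
    if mode not in ("per_feature", "concatenated"):
        raise ValueError(f"mode must be 'per_feature' or 'concatenated', got {mode!r}")
    if not subgroups:
        raise ValueError("subgroups must be non-empty")
    feature_names = pair.schema.feature_names

    results: list[TimeSeriesDisparityResult] = []
    for sg in subgroups:
        if _series_missing(pair.real, sg):
            results.append(
                TimeSeriesDisparityResult(
                    sg, metric, None, None, None, None, flags=("empty_in_real",)
                )
            )
            continue
        if _series_missing(pair.synthetic, sg):
            results.append(
                TimeSeriesDisparityResult(
                    sg, metric, None, None, None, CategoryLevel.MISSING,
                    flags=("missing_in_synthetic",),
                )
            )
            continue
        try:
            real_g1 = aggregate_series(pair.real, sg, statistic)
            synt_g1 = aggregate_series(pair.synthetic, sg, statistic)
            real_g0 = aggregate_series(pair.real, sg, statistic, complement=True)
            synt_g0 = aggregate_series(pair.synthetic, sg, statistic, complement=True)
        except EmptySubgroupError:
            results.append(
                TimeSeriesDisparityResult(
                    sg, metric, None, None, None, None, flags=("empty_complement",)
                )
            )
            continue

        flags: list[str] = []
        if mode == "concatenated":
            cat = lambda d: np.concatenate([d[f] for f in feature_names])  # noqa: E731
            res_g1, reason1 = _safe_res(cat(real_g1), cat(synt_g1), metric)
            res_g0, reason0 = _safe_res(cat(real_g0), cat(synt_g0), metric)
            per_feature = None
        else:
            per_feature = {}
            vals_g1, vals_g0 = [], []
            for f in feature_names:
                r1, reason1 = _safe_res(real_g1[f], synt_g1[f], metric)
                r0, reason0 = _safe_res(real_g0[f], synt_g0[f], metric)
                ld_f: Optional[float] = None
                if r1 is not None and r0 is not None and r1 > 0 and r0 > 0:
                    ld_f = ts_log_disparity(r1, r0)
                per_feature[f] = (r1, r0, ld_f)
                if reason1:
                    flags.append(f"{f}:{reason1}_subgroup")
                if reason0:
                    flags.append(f"{f}:{reason0}_complement")
                if r1 is not None:
                    vals_g1.append(r1)
                if r0 is not None:
                    vals_g0.append(r0)
            res_g1 = float(np.mean(vals_g1)) if vals_g1 else None
            res_g0 = float(np.mean(vals_g0)) if vals_g0 else None
            reason1 = reason0 = None

        if mode == "concatenated":
            if reason1:
                flags.append(f"{reason1}_subgroup")
            if reason0:
                flags.append(f"{reason0}_complement")

        ld: Optional[float] = None
        category: Optional[CategoryLevel] = None
        if res_g1 is None or res_g0 is None:
            flags.append("undefined_resemblance")
        elif res_g1 == 0:
            category = CategoryLevel.HIGHLY_UNDER
            flags.append("zero_resemblance")
        elif res_g0 == 0:
            category = CategoryLevel.HIGHLY_OVER
            flags.append("zero_resemblance")
        else:
            ld = ts_log_disparity(res_g1, res_g0)
            category = categorize(ld, scale)
        results.append(
            TimeSeriesDisparityResult(
                sg, metric, res_g1, res_g0, ld, category,
                per_feature=per_feature, flags=tuple(flags),
            )
        )
    return results


def timeseries_results_to_frame(results: list[TimeSeriesDisparityResult]):
    """Long-format table: one row per (subgroup, feature) plus summary rows."""
    import pandas as pd

    from .rate_disparity import CATEGORY_COLORS

    rows = []
    for r in results:
        if r.per_feature:
            for f, (r1, r0, ld) in r.per_feature.items():
                cat = categorize(ld) if ld is not None else None
                rows.append(
                    {
                        "subgroup": r.subgroup.label(),
                        "feature": f,
                        "metric": r.metric,
                        "res_subgroup": np.nan if r1 is None else r1,
                        "res_complement": np.nan if r0 is None else r0,
                        "ts_log_disparity": np.nan if ld is None else ld,
                        "category": cat.value if cat else "",
                        "color": CATEGORY_COLORS[cat] if cat else "",
                        "flags": ";".join(fl for fl in r.flags if fl.startswith(f"{f}:")),
                    }
                )
        rows.append(
            {
                "subgroup": r.subgroup.label(),
                "feature": CONCATENATED if r.per_feature is None else "mean_over_features",
                "metric": r.metric,
                "res_subgroup": np.nan if r.res_g1 is None else r.res_g1,
                "res_complement": np.nan if r.res_g0 is None else r.res_g0,
                "ts_log_disparity": np.nan if r.ts_log_disparity is None else r.ts_log_disparity,
                "category": r.category.value if r.category else "",
                "color": CATEGORY_COLORS[r.category] if r.category else "",
                "flags": ";".join(fl for fl in r.flags if ":" not in fl),
            }
        )
    return pd.DataFrame(rows)
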