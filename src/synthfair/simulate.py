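"""Paired real/synthetic dataset generation with known, parametric bias.

Real-world audits compare a real table against the output of a generative
model. For testing and demonstration this module plays the generative model:
the "real" table is sampled from a declared joint distribution over the
protected-attribute cells, and the "synthetic" table is sampled from the
same joint after multiplying the sampling *odds* of chosen subgroups by a
factor omega. Because the bias is injected on odds, omega is exactly the
disparity ratio the rate metric estimates — generate with omega = 0.8 and a
correct implementation recovers log disparity ln(0.8) for that subgroup.
omega = 0 deletes the subgroup from the synthetic table (mode collapse) and
must surface as the missing category.

Temporal columns are filled from smooth per-cell base curves. Real rows get
the base curve plus iid Gaussian noise (or Bernoulli draws around a
prevalence curve for binary templates); synthetic rows follow the same curve
but each step's direction is flipped independently with a configurable
probability, optionally only for rows of one target subgroup. A flip
probability of 0.5 destroys directional information (DS -> ~50) and linear
correlation (mapped PCC -> ~0.5) for the targeted subgroup while leaving the
complement intact.

Three presets mirror common audit shapes: an ICU mortality extract (race 5,
gender 2, age 4 bins, 30-day mortality 2 — no temporal block), a time-use
sleep survey (gender 2, age 7 bins, one 30-point average-sleep series) and a
pediatric claims panel (gender, race, seven binary diagnosis series over 10
half-year periods).

Everything is deterministic for a fixed seed (one global seed, split per
table via numpy SeedSequence.spawn).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import DatasetPair, DatasetSchema, TabularDataset, make_pair
from .errors import BiasSpecError
from .subgroups import SubgroupDefinition

Cell = tuple[str, ...]


@dataclass(frozen=True)
class TemporalSpec:
    """How temporal columns are synthesised.

    template
        "sleep" (smooth continuous curves, minutes-scale), "prevalence"
        (per-period probabilities in (0,1), rows drawn as Bernoulli) or
        "linear" (a plain ramp; handy for exact-value tests).
    noise_sd
        SD of iid Gaussian noise added to every continuous entry.
    direction_flip_prob
        Per-step probability that a synthetic row's increment has its sign
        flipped.
    flip_subgroup
        Restrict flips to rows matching this {attr: level} assignment;
        None applies the flip probability to every synthetic row.
    """

    template: str = "sleep"
    noise_sd: float = 0.0
    direction_flip_prob: float = 0.0
    flip_subgroup: Optional[tuple[tuple[str, str], ...]] = None

    def __post_init__(self):
        if self.template not in ("sleep", "prevalence", "linear"):
            raise BiasSpecError(f"unknown temporal template {self.template!r}")
        if self.noise_sd < 0:
            raise BiasSpecError("noise_sd must be >= 0")
        if not 0 <= self.direction_flip_prob <= 1:
            raise BiasSpecError("direction_flip_prob must lie in [0, 1]")
        if isinstance(self.flip_subgroup, dict):
            object.__setattr__(self, "flip_subgroup", tuple(sorted(self.flip_subgroup.items())))


@dataclass(frozen=True)
class BiasSpec:
    """Ground-truth generating process for one real/synthetic pair.

    base_joint
        Probability of each protected-attribute cell (key: tuple of levels
        in schema attribute order). Cells may be omitted (probability 0);
        the present cells must sum to 1.
    odds_multipliers
        Ordered ``(assignment, omega)`` pairs; each multiplies the synthetic
        sampling odds of the matching subgroup by omega (> 0, or 0 to delete
        it) and renormalises. Applied sequentially.
    """

    base_joint: dict[Cell, float]
    odds_multipliers: tuple[tuple[tuple[tuple[str, str], ...], float], ...] = ()
    temporal: Optional[TemporalSpec] = None
    n_real: int = 10_000
    n_synthetic: int = 10_000
    seed: int = 0

    def __post_init__(self):
        total = float(sum(self.base_joint.values()))
        if any(v < 0 for v in self.base_joint.values()):
            raise BiasSpecError("base_joint cells must be non-negative")
        if abs(total - 1.0) > 1e-9:
            raise BiasSpecError(f"base_joint must sum to 1, got {total}")
        for assignment, omega in self.odds_multipliers:
            if omega < 0:
                raise BiasSpecError("odds multipliers must be >= 0")
        if self.n_real < 1 or self.n_synthetic < 1:
            raise BiasSpecError("sample sizes must be >= 1")

    @staticmethod
    def multiplier(assignment: dict[str, str], omega: float):
        """Convenience constructor for one odds_multipliers entry."""
        return (tuple(sorted(assignment.items())), float(omega))


def product_joint(schema: DatasetSchema, marginals: dict[str, list[float]]) -> dict[Cell, float]:
    """Build an independent (product-form) joint from per-attribute marginals."""
    probs_per_attr = []
    for attr, levels in schema.protected_attrs:
        p = marginals[attr]
        if len(p) != len(levels):
            raise BiasSpecError(f"marginal for {attr!r} must have {len(levels)} entries")
        s = float(sum(p))
        if s <= 0:
            raise BiasSpecError(f"marginal for {attr!r} must have positive mass")
        probs_per_attr.append([v / s for v in p])
    joint: dict[Cell, float] = {}
    for cell in itertools.product(*(levels for _, levels in schema.protected_attrs)):
        prob = 1.0
        for i, level in enumerate(cell):
            prob *= probs_per_attr[i][schema.protected_attrs[i][1].index(level)]
        joint[cell] = prob
    return joint


def _cell_matches(cell: Cell, schema: DatasetSchema, assignment: tuple[tuple[str, str], ...]) -> bool:
    idx = {a: i for i, a in enumerate(schema.attribute_names)}
    return all(cell[idx[attr]] == level for attr, level in assignment)


def reweight_joint(
    joint: dict[Cell, float],
    schema: DatasetSchema,
    odds_multipliers,
) -> dict[Cell, float]:
    """Multiply subgroup sampling odds by omega and renormalise, sequentially.

    For a subgroup with total mass p, the new mass is
    p' = omega p / (1 - p + omega p), so that odds(p') = omega * odds(p).
    Cells inside the subgroup scale by p'/p, cells outside by (1-p')/(1-p).
    """
    current = dict(joint)
    for assignment, omega in odds_multipliers:
        inside = {c for c in current if _cell_matches(c, schema, assignment)}
        p = sum(current[c] for c in inside)
        if p == 0:
            continue  # nothing to reweight
        if p == 1:
            raise BiasSpecError("cannot reweight a subgroup that is the entire population")
        p_new = omega * p / (1 - p + omega * p)
        scale_in = p_new / p
        scale_out = (1 - p_new) / (1 - p)
        current = {c: v * (scale_in if c in inside else scale_out) for c, v in current.items()}
    total = sum(current.values())
    if total <= 0 or not np.isfinite(total):
        raise BiasSpecError("re-weighting produced a non-normalizable joint")
    return {c: v / total for c, v in current.items()}


def _sample_cells(
    joint: dict[Cell, float], n: int, rng: np.random.Generator
) -> tuple[list[Cell], np.ndarray]:
    cells = list(joint.keys())
    probs = np.array([joint[c] for c in cells], dtype=float)
    probs = probs / probs.sum()
    counts = rng.multinomial(n, probs)
    return cells, counts


def _categorical_frame(
    schema: DatasetSchema, cells: list[Cell], counts: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    cols: dict[str, list[str]] = {a: [] for a in schema.attribute_names}
    for cell, count in zip(cells, counts):
        for i, attr in enumerate(schema.attribute_names):
            cols[attr].extend([cell[i]] * int(count))
    df = pd.DataFrame(cols)
    perm = rng.permutation(len(df))
    return df.iloc[perm].reset_index(drop=True)


def generate_categorical_pair(schema: DatasetSchema, spec: BiasSpec) -> DatasetPair:
    """Sample a real table from base_joint and a synthetic table from the
    odds-reweighted joint. Deterministic for a fixed spec.seed."""
    ss = np.random.SeedSequence(spec.seed)
    rng_real, rng_synth = (np.random.default_rng(s) for s in ss.spawn(2))
    synth_joint = reweight_joint(spec.base_joint, schema, spec.odds_multipliers)

    cells_r, counts_r = _sample_cells(spec.base_joint, spec.n_real, rng_real)
    cells_s, counts_s = _sample_cells(synth_joint, spec.n_synthetic, rng_synth)
    real_df = _categorical_frame(schema, cells_r, counts_r, rng_real)
    synth_df = _categorical_frame(schema, cells_s, counts_s, rng_synth)
    real = TabularDataset("real", real_df, schema)
    synth = TabularDataset("synthetic", synth_df, schema)
    return make_pair(real, synth, schema)


def _base_curve(template: str, feature_idx: int, cell_idx: int, T: int) -> np.ndarray:
    """Deterministic smooth base curve for one (feature, cell)."""
    k = np.arange(T, dtype=float)
    if template == "linear":
        return k + 3.0 * cell_idx
    if template == "sleep":
        # minutes-of-sleep-like daily curve; phase/amplitude vary by cell
        phase = 0.7 * cell_idx + 0.4 * feature_idx
        return (
            480.0
            + 12.0 * cell_idx
            + 45.0 * np.sin(2 * np.pi * k / T + phase)
            + 15.0 * np.cos(4 * np.pi * k / T + 0.5 * phase)
        )
    if template == "prevalence":
        phase = 0.9 * cell_idx + 0.6 * feature_idx
        base = 0.18 + 0.04 * (feature_idx % 4) + 0.02 * (cell_idx % 3)
        curve = base + 0.12 * np.sin(2 * np.pi * k / T + phase) + 0.01 * k
        return np.clip(curve, 0.03, 0.92)
    raise BiasSpecError(f"unknown temporal template {template!r}")


def _flip_series(
    base: np.ndarray, flip_mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Rebuild row series from base increments with signs flipped where masked.

    ``flip_mask`` has shape (rows, T-1); True flips that step's increment.
    """
    inc = np.diff(base)  # (T-1,)
    signed = np.where(flip_mask, -inc, inc)
    out = np.empty((flip_mask.shape[0], len(base)))
    out[:, 0] = base[0]
    out[:, 1:] = base[0] + np.cumsum(signed, axis=1)
    return out


def _temporal_block(
    schema: DatasetSchema,
    df: pd.DataFrame,
    temporal: TemporalSpec,
    cell_index: dict[Cell, int],
    rng: np.random.Generator,
    synthetic: bool,
) -> pd.DataFrame:
    n = len(df)
    attr_names = schema.attribute_names
    row_cells = list(zip(*(df[a] for a in attr_names)))
    cell_ids = np.array([cell_index[rc] for rc in row_cells])
    flip_target = None
    if temporal.flip_subgroup is not None:
        flip_target = SubgroupDefinition(tuple(
            (a, dict(temporal.flip_subgroup)[a])
            for a in attr_names if a in dict(temporal.flip_subgroup)
        ))
        flip_rows = flip_target.matches(df)
    else:
        flip_rows = np.ones(n, dtype=bool)

    data: dict[str, np.ndarray] = {}
    for f_idx, (feature, cols) in enumerate(schema.temporal_features):
        T = len(cols)
        block = np.empty((n, T))
        for cell, c_idx in cell_index.items():
            rows = cell_ids == c_idx
            r = int(rows.sum())
            if r == 0:
                continue
            base = _base_curve(temporal.template, f_idx, c_idx, T)
            if synthetic and temporal.direction_flip_prob > 0:
                flip = (
                    rng.random((r, T - 1)) < temporal.direction_flip_prob
                ) & flip_rows[rows][:, None]
                series = _flip_series(base, flip, rng)
            else:
                series = np.tile(base, (r, 1))
            if temporal.template == "prevalence":
                p = np.clip(series, 0.02, 0.98)
                series = (rng.random((r, T)) < p).astype(float)
            elif temporal.noise_sd > 0:
                series = series + rng.normal(0.0, temporal.noise_sd, size=(r, T))
            block[rows] = series
        for j, col in enumerate(cols):
            data[col] = block[:, j]
    out = df.copy()
    for col, vals in data.items():
        out[col] = vals
    return out


def generate_temporal_pair(schema: DatasetSchema, spec: BiasSpec) -> DatasetPair:
    """Categorical sampling as in :func:`generate_categorical_pair`, plus
    temporal columns from per-cell base curves with the spec's distortions."""
    if spec.temporal is None:
        raise BiasSpecError("spec.temporal must be set for a temporal pair")
    if not schema.temporal_features:
        raise BiasSpecError("schema declares no temporal features")
    ss = np.random.SeedSequence(spec.seed)
    rng_real, rng_synth, rng_tr, rng_ts = (np.random.default_rng(s) for s in ss.spawn(4))
    synth_joint = reweight_joint(spec.base_joint, schema, spec.odds_multipliers)

    cells_r, counts_r = _sample_cells(spec.base_joint, spec.n_real, rng_real)
    cells_s, counts_s = _sample_cells(synth_joint, spec.n_synthetic, rng_synth)
    real_df = _categorical_frame(schema, cells_r, counts_r, rng_real)
    synth_df = _categorical_frame(schema, cells_s, counts_s, rng_synth)

    all_cells = sorted(spec.base_joint.keys())
    cell_index = {c: i for i, c in enumerate(all_cells)}
    real_df = _temporal_block(schema, real_df, spec.temporal, cell_index, rng_tr, synthetic=False)
    synth_df = _temporal_block(schema, synth_df, spec.temporal, cell_index, rng_ts, synthetic=True)

    real = TabularDataset("real", real_df, schema)
    synth = TabularDataset("synthetic", synth_df, schema)
    return make_pair(real, synth, schema)


def generate_pair(schema: DatasetSchema, spec: BiasSpec) -> DatasetPair:
    """Dispatch on whether the schema/spec carry a temporal block."""
    if schema.temporal_features and spec.temporal is not None:
        return generate_temporal_pair(schema, spec)
    return generate_categorical_pair(schema, spec)


def null_level_counts(
    probs: np.ndarray, n: int, replicates: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Fast path for null-calibration studies.

    Both arms are drawn from the same multinomial; returns two arrays of
    shape (replicates, n_levels) of level counts — the sufficient statistics
    for every univariate subgroup test, avoiding materialising full tables.
    """
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()
    real = rng.multinomial(n, probs, size=replicates)
    synth = rng.multinomial(n, probs, size=replicates)
    return real, synth


def independent_population(
    rng: np.random.Generator, max_cell: int = 20, max_weight: int = 6
) -> pd.DataFrame:
    """Finite (g, y, y') population satisfying the odds-ratio identity exactly.

    ``y`` marks membership in the real sample, ``y'`` in the synthetic
    sample, ``g`` in the protected subgroup. The disparate-impact /
    odds-ratio equivalence requires y independent of both y' and g; that
    holds *exactly in the empirical distribution* when the joint factorises
    as P(y) x P(g, y'). The table is built in that product form: integer
    counts c(g, y') over the four (g, y') cells, each replicated ``a`` times
    with y=1 and ``b`` times with y=0. All four (g, y') cells are kept
    nonzero so no conditional frequency degenerates.
    """
    c = rng.integers(1, max_cell, size=4)  # cells: (g,y') in (1,1),(1,0),(0,1),(0,0)
    a, b = int(rng.integers(1, max_weight)), int(rng.integers(1, max_weight))
    g_vals, yp_vals = (1, 1, 0, 0), (1, 0, 1, 0)
    rows = []
    for cell, g, yp in zip(c, g_vals, yp_vals):
        rows.append((g, 1, yp, int(cell) * a))
        rows.append((g, 0, yp, int(cell) * b))
    g_col, y_col, yp_col = [], [], []
    for g, y, yp, count in rows:
        g_col.extend([g] * count)
        y_col.extend([y] * count)
        yp_col.extend([yp] * count)
    return pd.DataFrame({"g": g_col, "y": y_col, "yprime": yp_col})


# ---------------------------------------------------------------------------
# Presets mirroring the three audit shapes
# ---------------------------------------------------------------------------

def mimic_like_schema() -> DatasetSchema:
    """ICU mortality extract shape: race 5, gender 2, age 4 bins, mortality 2."""
    return DatasetSchema(
        protected_attrs=(
            ("race", ("Asian", "Black", "Hispanic", "White", "Other")),
            ("gender", ("Male", "Female")),
            ("age", ("18-50", "51-65", "66-80", "81+")),
            ("mortality", ("Alive", "Died")),
        )
    )


def atus_like_schema() -> DatasetSchema:
    """Time-use sleep survey shape: gender 2, age 7 bins, 30-point sleep series."""
    return DatasetSchema(
        protected_attrs=(
            ("gender", ("Male", "Female")),
            ("age", ("15-24", "25-34", "35-44", "45-54", "55-64", "65-74", "75+")),
        ),
        temporal_features=(("sleep", tuple(f"sleep_t{k:02d}" for k in range(30))),),
        aggregation_statistic="mean",
    )


def asd_like_schema() -> DatasetSchema:
    """Pediatric claims panel: gender, race; 7 binary diagnosis series x 10 periods."""
    features = ("adhd", "dd", "gastro", "immune", "psychiatric", "seizure", "sleep_disorder")
    return DatasetSchema(
        protected_attrs=(
            ("gender", ("Male", "Female")),
            ("race", ("Asian", "Black", "Hispanic", "White")),
        ),
        temporal_features=tuple(
            (f, tuple(f"{f}_p{k}" for k in range(10))) for f in features
        ),
        aggregation_statistic="mean",
    )


def preset_spec(name: str, n_real: int = 10_000, n_synthetic: int = 10_000, seed: int = 0,
                odds_multipliers=(), temporal_overrides: Optional[dict] = None) -> tuple[DatasetSchema, BiasSpec]:
    """Schema + default BiasSpec for one of the three preset shapes."""
    if name == "mimic":
        schema = mimic_like_schema()
        joint = product_joint(schema, {
            "race": [0.04, 0.12, 0.06, 0.70, 0.08],
            "gender": [0.55, 0.45],
            "age": [0.30, 0.25, 0.30, 0.15],
            "mortality": [0.70, 0.30],
        })
        temporal = None
    elif name == "atus":
        schema = atus_like_schema()
        joint = product_joint(schema, {
            "gender": [0.4303, 0.5697],
            "age": [0.15, 0.17, 0.16, 0.17, 0.15, 0.11, 0.09],
        })
        temporal = TemporalSpec(template="sleep", noise_sd=5.0)
    elif name == "asd":
        schema = asd_like_schema()
        joint = product_joint(schema, {
            "gender": [0.80, 0.20],
            "race": [0.05, 0.15, 0.20, 0.60],
        })
        temporal = TemporalSpec(template="prevalence")
    else:
        raise BiasSpecError(f"unknown preset {name!r} (expected mimic, atus or asd)")
    if temporal is not None and temporal_overrides:
        from dataclasses import replace

        temporal = replace(temporal, **temporal_overrides)
    spec = BiasSpec(
        base_joint=joint,
        odds_multipliers=tuple(odds_multipliers),
        temporal=temporal,
        n_real=n_real,
        n_synthetic=n_synthetic,
        seed=seed,
    )
    return schema, spec
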