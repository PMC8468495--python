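"""Schema and dataset containers for paired real/synthetic tabular data.

A :class:`DatasetSchema` declares which columns are protected attributes
(categorical, with a closed set of levels), which columns form ordered
temporal feature blocks (``m`` features x ``T`` time columns each), and the
statistic used to aggregate temporal columns within a subgroup. Everything
else in a table is carried along as unprotected attributes and ignored by
the metrics.

Datasets are plain pandas DataFrames wrapped with a role tag. Validation is
strict: an unseen protected level, a missing schema column or a non-numeric
temporal cell is a hard error — silently coercing any of these would corrupt
the subgroup enumeration or the aggregated series downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml

from .errors import ConfigurationError, LevelError, ParseError, SchemaError

Role = Literal["real", "synthetic"]

AGGREGATION_STATISTICS = ("mean", "count", "sum")


@dataclass(frozen=True)
class DatasetSchema:
    """Declares protected attributes, temporal feature blocks and aggregation.

    Parameters
    ----------
    protected_attrs
        Ordered ``(name, levels)`` pairs. Level order is preserved and used
        for deterministic subgroup enumeration.
    temporal_features
        Ordered ``(feature name, column names)`` pairs; the columns of one
        feature are its time points in temporal order.
    aggregation_statistic
        One of ``"mean"``, ``"count"``, ``"sum"`` — the function *f* used to
        collapse a subgroup's rows into one series per feature.
    id_column
        Optional identifier column, carried but ignored by all metrics.
    """

    protected_attrs: tuple[tuple[str, tuple[str, ...]], ...]
    temporal_features: tuple[tuple[str, tuple[str, ...]], ...] = ()
    aggregation_statistic: str = "mean"
    id_column: str | None = None

    def __post_init__(self):
        if not self.protected_attrs:
            raise SchemaError("schema must declare at least one protected attribute")
        object.__setattr__(
            self,
            "protected_attrs",
            tuple((str(a), tuple(str(l) for l in levels)) for a, levels in self.protected_attrs),
        )
        object.__setattr__(
            self,
            "temporal_features",
            tuple((str(f), tuple(str(c) for c in cols)) for f, cols in self.temporal_features),
        )
        names = [a for a, _ in self.protected_attrs]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate protected attribute names")
        for attr, levels in self.protected_attrs:
            if not levels:
                raise SchemaError(f"attribute {attr!r} has an empty level list")
            if len(set(levels)) != len(levels):
                raise SchemaError(f"attribute {attr!r} has duplicate levels")
        seen: set[str] = set(names)
        for feat, cols in self.temporal_features:
            if not cols:
                raise SchemaError(f"temporal feature {feat!r} has no columns")
            for c in cols:
                if c in seen:
                    raise SchemaError(f"temporal column {c!r} clashes with another schema column")
                seen.add(c)
        if self.aggregation_statistic not in AGGREGATION_STATISTICS:
            raise SchemaError(
                f"aggregation_statistic must be one of {AGGREGATION_STATISTICS}, "
                f"got {self.aggregation_statistic!r}"
            )

    @property
    def attribute_names(self) -> tuple[str, ...]:
        return tuple(a for a, _ in self.protected_attrs)

    def levels_of(self, attr: str) -> tuple[str, ...]:
        for a, levels in self.protected_attrs:
            if a == attr:
                return levels
        raise SchemaError(f"unknown protected attribute {attr!r}")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(f for f, _ in self.temporal_features)

    def columns_of(self, feature: str) -> tuple[str, ...]:
        for f, cols in self.temporal_features:
            if f == feature:
                return cols
        raise SchemaError(f"unknown temporal feature {feature!r}")

    @property
    def temporal_columns(self) -> tuple[str, ...]:
        return tuple(c for _, cols in self.temporal_features for c in cols)

    def required_columns(self) -> tuple[str, ...]:
        cols = list(self.attribute_names) + list(self.temporal_columns)
        return tuple(cols)

    def to_dict(self) -> dict:
        return {
            "protected_attributes": [
                {"name": a, "levels": list(levels)} for a, levels in self.protected_attrs
            ],
            "temporal_features": [
                {"name": f, "columns": list(cols)} for f, cols in self.temporal_features
            ],
            "aggregation_statistic": self.aggregation_statistic,
            "id_column": self.id_column,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetSchema":
        try:
            attrs = tuple(
                (item["name"], tuple(item["levels"])) for item in d["protected_attributes"]
            )
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"malformed schema config: {exc}") from exc
        feats = tuple(
            (item["name"], tuple(item["columns"])) for item in d.get("temporal_features") or ()
        )
        return cls(
            protected_attrs=attrs,
            temporal_features=feats,
            aggregation_statistic=d.get("aggregation_statistic", "mean"),
            id_column=d.get("id_column"),
        )


def load_schema(path: str | Path) -> DatasetSchema:
    """Read a schema config (YAML/JSON mapping mirroring DatasetSchema)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise SchemaError(f"schema config {path} is not a mapping")
    return DatasetSchema.from_dict(doc)


def save_schema(schema: DatasetSchema, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(schema.to_dict(), fh, sort_keys=False)


@dataclass
class TabularDataset:
    """One validated table (real or synthetic) bound to a schema."""

    role: Role
    records: pd.DataFrame
    schema: DatasetSchema = field(repr=False)

    def __post_init__(self):
        if self.role not in ("real", "synthetic"):
            raise ConfigurationError(f"role must be 'real' or 'synthetic', got {self.role!r}")
        validate_records(self.records, self.schema)

    @property
    def n(self) -> int:
        return len(self.records)


@dataclass
class DatasetPair:
    """A real table and a synthetic table sharing one schema."""

    schema: DatasetSchema
    real: TabularDataset
    synthetic: TabularDataset

    def __post_init__(self):
        if self.real.role != "real" or self.synthetic.role != "synthetic":
            raise ConfigurationError(
                f"pair roles must be (real, synthetic), got "
                f"({self.real.role!r}, {self.synthetic.role!r})"
            )
        if self.real.schema != self.schema or self.synthetic.schema != self.schema:
            raise ConfigurationError("both datasets must be bound to the pair's schema")


def validate_records(df: pd.DataFrame, schema: DatasetSchema) -> None:
    """Validate a DataFrame against a schema; raise on the first violation."""
    if len(df) < 1:
        raise SchemaError("dataset must contain at least one row")
    for col in schema.required_columns():
        if col not in df.columns:
            raise SchemaError(f"missing schema column {col!r}")
    for attr in schema.attribute_names:
        levels = set(schema.levels_of(attr))
        bad = (~df[attr].astype(str).isin(levels) | df[attr].isna()).to_numpy()
        if bad.any():
            pos = int(bad.argmax())
            raise LevelError(
                f"row {pos}, column {attr!r}: value {df[attr].iloc[pos]!r} "
                f"is not a declared level"
            )
    for col in schema.temporal_columns:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = (~values.map(math.isfinite)).to_numpy()
        if bad.any():
            pos = int(bad.argmax())
            raise ParseError(f"row {pos}, column {col!r}: non-numeric or non-finite temporal value")


def load_dataset(path: str | Path, schema: DatasetSchema, role: Role) -> TabularDataset:
    """Load a delimited-text table and validate it against ``schema``.

    The file must be UTF-8, comma-separated, with a header row naming all
    schema columns. Extra columns are retained as unprotected attributes.
    Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={a: str for a in schema.attribute_names}, encoding="utf-8")
    for col in schema.temporal_columns:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return TabularDataset(role=role, records=df, schema=schema)


def save_dataset(dataset: TabularDataset, path: str | Path) -> None:
    """Write the records back to CSV (UTF-8, comma, header, '.' decimal)."""
    dataset.records.to_csv(path, index=False, encoding="utf-8")


def make_pair(
    real: TabularDataset, synthetic: TabularDataset, schema: DatasetSchema
) -> DatasetPair:
    """Bind a validated real and synthetic dataset into a pair.

    The two tables may have different row counts — real and synthetic data
    are independent samples, not row-aligned.
    """
    return DatasetPair(schema=schema, real=real, synthetic=synthetic)
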