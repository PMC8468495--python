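"""Subgroup lattice over protected attributes.

A subgroup is a conjunction of single attribute levels, e.g.
``gender=Female & age=75+``. Its membership function g(x) is 1 for a row
matching every assigned level and 0 otherwise; the complement g(x)=0 is
always *all remaining rows of the same dataset*, never a sibling level.

For a schema with attributes carrying L1, ..., Ld levels, the full lattice
has prod(Li + 1) - 1 subgroups (each attribute is either unassigned or fixed
to one of its levels, minus the empty assignment).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .data_model import DatasetSchema, TabularDataset
from .errors import SchemaError

MaxOrder = int | Literal["all"]


@dataclass(frozen=True)
class SubgroupDefinition:
    """A partial assignment of levels to protected attributes.

    ``assignment`` is stored as a tuple of ``(attribute, level)`` pairs in
    schema attribute order; equality is equality of assignments.
    """

    assignment: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if not self.assignment:
            raise ValueError("subgroup assignment must be non-empty")
        attrs = [a for a, _ in self.assignment]
        if len(set(attrs)) != len(attrs):
            raise ValueError("subgroup assigns the same attribute twice")

    @classmethod
    def from_mapping(cls, mapping: dict[str, str], schema: DatasetSchema) -> "SubgroupDefinition":
        """Build a definition from ``{attr: level}``, validated and ordered by schema."""
        for attr, level in mapping.items():
            if level not in schema.levels_of(attr):  # levels_of raises on bad attr
                raise SchemaError(f"{level!r} is not a level of attribute {attr!r}")
        ordered = tuple((a, mapping[a]) for a in schema.attribute_names if a in mapping)
        return cls(assignment=ordered)

    @property
    def order(self) -> int:
        return len(self.assignment)

    @property
    def attributes(self) -> tuple[str, ...]:
        return tuple(a for a, _ in self.assignment)

    def as_dict(self) -> dict[str, str]:
        return dict(self.assignment)

    def label(self) -> str:
        """Serialized form used in reports: ``attr=level&attr=level``."""
        return "&".join(f"{a}={l}" for a, l in self.assignment)

    def matches(self, df: pd.DataFrame) -> np.ndarray:
        """Boolean membership vector g(x) over the rows of ``df``."""
        mask = np.ones(len(df), dtype=bool)
        for attr, level in self.assignment:
            if attr not in df.columns:
                raise SchemaError(f"attribute {attr!r} absent from dataset")
            mask &= (df[attr].astype(str) == level).to_numpy()
        return mask


def enumerate_subgroups(schema: DatasetSchema, max_order: MaxOrder = "all") -> list[SubgroupDefinition]:
    """Enumerate all subgroups up to ``max_order`` assigned attributes.

    Ordering is deterministic: by order ascending, then by attribute position
    in the schema, then by level position. ``max_order="all"`` uses every
    protected attribute.
    """
    d = len(schema.protected_attrs)
    if max_order == "all":
        max_order = d
    if not isinstance(max_order, int) or max_order < 1:
        raise ValueError(f"max_order must be a positive integer or 'all', got {max_order!r}")
    if max_order > d:
        raise ValueError(f"max_order {max_order} exceeds the {d} protected attributes")

    out: list[SubgroupDefinition] = []
    for order in range(1, max_order + 1):
        for attr_combo in itertools.combinations(schema.protected_attrs, order):
            for levels in itertools.product(*(levels for _, levels in attr_combo)):
                assignment = tuple((a, l) for (a, _), l in zip(attr_combo, levels))
                out.append(SubgroupDefinition(assignment=assignment))
    return out


def membership_counts(dataset: TabularDataset, subgroup: SubgroupDefinition) -> tuple[int, int]:
    """Return ``(count_in, count_out)`` for g(x)=1 / g(x)=0 in the dataset."""
    mask = subgroup.matches(dataset.records)
    count_in = int(mask.sum())
    return count_in, dataset.n - count_in


def complement_mask(dataset: TabularDataset, subgroup: SubgroupDefinition) -> np.ndarray:
    """Boolean vector for the complement group g(x)=0."""
    return ~subgroup.matches(dataset.records)


def lattice_size(schema: DatasetSchema) -> int:
    """Closed-form size of the full subgroup lattice: prod(Li + 1) - 1."""
    size = 1
    for _, levels in schema.protected_attrs:
        size *= len(levels) + 1
    return size - 1


def parse_label(label: str, schema: DatasetSchema) -> SubgroupDefinition:
    """Inverse of :meth:`SubgroupDefinition.label`."""
    mapping: dict[str, str] = {}
    for part in label.split("&"):
        attr, _, level = part.partition("=")
        if not level:
            raise ValueError(f"malformed subgroup label part {part!r}")
        mapping[attr] = level
    return SubgroupDefinition.from_mapping(mapping, schema)


def subgroups_from_specs(
    specs: Iterable[dict[str, str]], schema: DatasetSchema
) -> list[SubgroupDefinition]:
    return [SubgroupDefinition.from_mapping(s, schema) for s in specs]
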