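"""Exporters: flat result tables and hierarchical sunburst data.

The canonical outputs are data artifacts — a CSV table per metric and a
nested JSON tree for sunburst rendering — so any front end (matplotlib,
plotly, an R app) can draw them. Rendering itself is deliberately out of
this module.
"""

from __future__ import annotations

import json
import logging
import warnings
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

from .data_model import DatasetSchema
from .errors import ConfigurationError
from .rate_disparity import CATEGORY_COLORS, RateDisparityResult, results_to_frame
from .timeseries import TimeSeriesDisparityResult, timeseries_results_to_frame

log = logging.getLogger("synthfair")


def export_rate_table(results: list[RateDisparityResult], path: str | Path) -> Path:
    """Write the flat rate-disparity table (one row per subgroup) as CSV.

    Includes the category color column (missing = red) and a ``starred``
    column marking subgroups whose real/synthetic difference was *not*
    statistically significant after adjustment.
    """
    path = Path(path)
    frame = results_to_frame(results)
    if frame.empty:
        warnings.warn("no rate-disparity results to export; writing header only")
    frame.to_csv(path, index=False)
    return path


def export_timeseries_table(
    results: list[TimeSeriesDisparityResult], path: str | Path
) -> Path:
    """Write the long-format time-series disparity table as CSV."""
    path = Path(path)
    timeseries_results_to_frame(results).to_csv(path, index=False)
    return path


def build_sunburst(
    results: list[RateDisparityResult],
    hierarchy: Sequence[str],
    schema: DatasetSchema,
) -> dict:
    """Nest rate results into a sunburst tree along a ring hierarchy.

    Ring k holds the order-k subgroups whose assigned attributes are the
    first k attributes of ``hierarchy``; a node's children extend its
    assignment by the next attribute's levels. Only subgroups present in the
    results (i.e. evaluable against the real data) appear; a leaf that is
    missing from the synthetic data carries category "missing".
    """
    hierarchy = list(hierarchy)
    for attr in hierarchy:
        schema.levels_of(attr)  # raises SchemaError on unknown attribute
    by_assignment = {tuple(sorted(r.subgroup.assignment)): r for r in results}
    needed_orders = set(range(1, len(hierarchy) + 1))
    present_orders = {r.subgroup.order for r in results}
    if not needed_orders <= present_orders:
        raise ConfigurationError(
            f"results lack subgroups of orders {sorted(needed_orders - present_orders)} "
            f"needed for a {len(hierarchy)}-ring hierarchy"
        )

    def node_for(assignment: tuple[tuple[str, str], ...], depth: int) -> Optional[dict]:
        res = by_assignment.get(tuple(sorted(assignment)))
        if res is None:
            return None  # not evaluable (absent from real data)
        node = {
            "name": assignment[-1][1],
            "attribute": assignment[-1][0],
            "subgroup": res.subgroup.label(),
            "count_real": res.count_R,
            "count_synthetic": res.count_S,
            "log_disparity": res.log_disparity,
            "category": res.category.value,
            "color": CATEGORY_COLORS[res.category],
            "significant": res.significant,
        }
        if depth < len(hierarchy):
            children = []
            for level in schema.levels_of(hierarchy[depth]):
                child = node_for(assignment + ((hierarchy[depth], level),), depth + 1)
                if child is not None:
                    children.append(child)
            node["children"] = children
        return node

    roots = []
    for level in schema.levels_of(hierarchy[0]):
        root = node_for(((hierarchy[0], level),), 1)
        if root is not None:
            roots.append(root)
    return {"hierarchy": hierarchy, "children": roots}


def export_sunburst(
    results: list[RateDisparityResult],
    hierarchy: Sequence[str],
    schema: DatasetSchema,
    path: str | Path,
) -> Path:
    path = Path(path)
    tree = build_sunburst(results, hierarchy, schema)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(tree, fh, indent=2)
    return path


def run_metadata(
    schema: DatasetSchema, options: dict, seed: Optional[int] = None, freeze_timestamp: bool = False
) -> dict:
    """Run header written alongside every report bundle."""
    return {
        "schema": schema.to_dict(),
        "options": options,
        "seed": seed,
        "timestamp": "frozen" if freeze_timestamp
        else datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "category_palette": {k.value: v for k, v in CATEGORY_COLORS.items()},
    }


def export_metadata(meta: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)
    return path
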