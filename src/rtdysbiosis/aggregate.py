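"""Collapse a species-level abundance table to genus or family level.

Counts are summed within each higher-level label via a species -> lineage
map, so per-sample totals are conserved exactly and aggregation commutes
with conversion to relative abundance. Unclassified species are carried
under their synthesized labels (e.g. ``unclassified_<parent>``) rather than
dropped.
"""

from __future__ import annotations

import pandas as pd

from .containers import AbundanceTable

LEVELS = ("species", "genus", "family")

__all__ = ["LEVELS", "aggregate", "aggregate_all_levels"]


def aggregate(table: AbundanceTable, lineage: pd.DataFrame, level: str) -> AbundanceTable:
    """Sum abundances within each ``level`` label of the lineage map.

    ``lineage`` is indexed by species id with ``genus`` and ``family``
    columns (see :func:`rtdysbiosis.io.read_lineage_tsv`); ``level='species'``
    returns a copy. Any table taxon missing from the map raises.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    if level == "species":
        return AbundanceTable(table.values.copy(), unit=table.unit)
    missing = [t for t in table.taxon_ids if t not in lineage.index]
    if missing:
        raise ValueError(f"taxon {missing[0]!r} is not in the lineage map")
    labels = lineage.loc[table.taxon_ids, level]
    out = table.values.groupby(labels.to_numpy()).sum()
    out.index.name = "taxon_id"
    return AbundanceTable(out, unit=table.unit)


def aggregate_all_levels(table: AbundanceTable, lineage: pd.DataFrame) -> dict:
    """Tables at species, genus and family level, as a dict keyed by level."""
    return {level: aggregate(table, lineage, level) for level in LEVELS}
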