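"""Microbial Community Polarization Index (MCPI).

A per-sample dysbiosis score contrasting the product of abundances of taxa
representative of the toxicity phenotype (set T) against those of the
no-toxicity phenotype (set N):

    MCPI_j = ln( prod_{i in T} (A_ij + c) / (prod_{i in N} (A_ij + c) + eps) + 1 )

where A_ij is the relative abundance of taxon i in sample j, ``c`` a
pseudocount guarding the products against zeros, and ``eps`` a denominator
stabilizer. With c = eps = 0 this is the literal log-ratio form; MCPI is
always finite and >= 0, equals ln 2 exactly when the two products balance
(eps = 0), grows as the community polarizes toward T, and shrinks toward 0
as it polarizes toward N.

The T/N sets may mix taxonomic levels (family + genus + species
representatives, each taxon read from its own level's table) or be taken
from a single level; both modes are supported because published usage is
ambiguous between them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import AbundanceTable, CohortMetadata
from .stats import one_way_anova

__all__ = ["MCPIConfig", "MCPIScorer", "compute_mcpi", "compare_mcpi_by_timepoint"]

#: a taxon reference is either a bare taxon id (single-table mode) or a
#: (level, taxon id) pair (mixed-level mode)
TaxonRef = str | tuple


@dataclass
class MCPIConfig:
    """Taxon sets and numerical guards defining the index."""

    T: Sequence[TaxonRef]
    N: Sequence[TaxonRef]
    epsilon: float = 1e-8
    pseudocount: float = 1e-6

    def __post_init__(self) -> None:
        self.T = tuple(self.T)
        self.N = tuple(self.N)
        if not self.T or not self.N:
            raise ValueError("T and N must both be non-empty")
        if set(self.T) & set(self.N):
            raise ValueError("T and N must be disjoint")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


def _abundance_rows(
    tables: AbundanceTable | Mapping[str, AbundanceTable],
    refs: Sequence[TaxonRef],
) -> np.ndarray:
    """Stack the relative-abundance rows named by ``refs`` (taxa x samples)."""
    rows = []
    for ref in refs:
        if isinstance(ref, tuple):
            level, taxon = ref
            if not isinstance(tables, Mapping):
                raise ValueError(
                    f"taxon {ref!r} is level-qualified but a single table was given"
                )
            if level not in tables:
                raise ValueError(f"no table provided for level {level!r}")
            table = tables[level]
        else:
            taxon = ref
            table = tables if not isinstance(tables, Mapping) else None
            if table is None:
                raise ValueError(
                    f"taxon {ref!r} is unqualified but per-level tables were given"
                )
        rel = table if table.unit == "proportions" else table.relative_abundance()
        if taxon not in rel.values.index:
            raise ValueError(f"taxon {taxon!r} missing from its abundance table")
        rows.append(rel.values.loc[taxon].to_numpy())
    return np.array(rows)


class MCPIScorer(BaseEstimator, TransformerMixin):
    """Transform a proportion table into per-sample MCPI values."""

    def __init__(self, config: MCPIConfig | None = None, **kwargs):
        self.config = config if config is not None else MCPIConfig(**kwargs)

    def fit(self, X=None, y=None):
        return self

    def transform(
        self, tables: AbundanceTable | Mapping[str, AbundanceTable]
    ) -> pd.Series:
        cfg = self.config
        t_rows = _abundance_rows(tables, cfg.T)
        n_rows = _abundance_rows(tables, cfg.N)
        num = np.prod(t_rows + cfg.pseudocount, axis=0)
        den = np.prod(n_rows + cfg.pseudocount, axis=0) + cfg.epsilon
        mcpi = np.log(num / den + 1.0)
        any_table = tables[next(iter(tables))] if isinstance(tables, Mapping) else tables
        return pd.Series(mcpi, index=any_table.sample_ids, name="mcpi")


def compute_mcpi(
    tables: AbundanceTable | Mapping[str, AbundanceTable],
    config: MCPIConfig,
    metadata: CohortMetadata | None = None,
) -> pd.DataFrame:
    """Per-sample MCPI series, annotated with timepoint/toxicity if available.

    ``tables`` is a single proportion table, or a mapping level -> table when
    the T/N sets are level-qualified. Returns a DataFrame with columns
    sample_id, mcpi and (when metadata is given) timepoint and toxicity.
    """
    series = MCPIScorer(config).transform(tables)
    out = series.rename_axis("sample_id").reset_index()
    if metadata is not None:
        meta = metadata.indexed()
        missing = [s for s in out["sample_id"] if s not in meta.index]
        if missing:
            raise KeyError(f"samples missing from metadata: {missing[:5]}")
        out["timepoint"] = meta.loc[out["sample_id"], "timepoint"].to_numpy()
        out["toxicity"] = meta.loc[out["sample_id"], "toxicity"].to_numpy()
    return out


def compare_mcpi_by_timepoint(
    series: pd.DataFrame, timepoint_order: Sequence[str] | None = None
) -> pd.DataFrame:
    """One-way ANOVA of MCPI between toxicity groups at each timepoint.

    Timepoints where one group is absent are skipped with a warning.
    Returns a DataFrame with columns timepoint, F, p_value, n_tox, n_notox.
    """
    required = {"mcpi", "timepoint", "toxicity"}
    if not required <= set(series.columns):
        raise ValueError(f"series must have columns {sorted(required)}")
    timepoints = (
        list(timepoint_order)
        if timepoint_order is not None
        else list(dict.fromkeys(series["timepoint"]))
    )
    rows = []
    for tp in timepoints:
        at = series[series["timepoint"] == tp]
        tox = at.loc[at["toxicity"] == 1, "mcpi"].to_numpy()
        notox = at.loc[at["toxicity"] == 0, "mcpi"].to_numpy()
        if tox.size == 0 or notox.size == 0:
            warnings.warn(f"timepoint {tp!r}: only one group present; skipped",
                          stacklevel=2)
            continue
        res = one_way_anova([tox, notox])
        rows.append(
            {
                "timepoint": tp,
                "F": res.statistic,
                "p_value": res.p_value,
                "n_tox": tox.size,
                "n_notox": notox.size,
            }
        )
    return pd.DataFrame(rows)
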