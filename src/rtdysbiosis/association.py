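"""Differential-abundance testing between toxicity groups.

Per taxonomic level: filter taxa by maximum relative abundance, Wilcoxon
rank-sum across samples grouped by toxicity, Benjamini-Hochberg correction
within the level, and a generalized fold change (gFC) — the mean difference
of matched quantiles of log10 abundance — as a robust signed effect size.
The representative taxon of each group at each level is the significant
taxon with the largest gFC toward that group; the T/N sets so selected feed
the MCPI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import AbundanceTable, CohortMetadata
from .stats import benjamini_hochberg, wilcoxon_rank_sum

DEFAULT_QUANTILES = tuple(np.round(np.arange(0.05, 1.0, 0.1), 2))
DEFAULT_PSEUDOCOUNT = 1e-5

__all__ = [
    "DEFAULT_QUANTILES",
    "DEFAULT_PSEUDOCOUNT",
    "RepresentativeSets",
    "filter_by_abundance",
    "generalized_fold_change",
    "AssociationTest",
    "associate",
    "select_representatives",
]


def filter_by_abundance(
    table: AbundanceTable, cutoff: float, mode: str = "max"
) -> AbundanceTable:
    """Keep taxa whose max (or mean) relative abundance is >= ``cutoff``."""
    if table.unit != "proportions":
        raise ValueError("abundance filter expects a proportion table")
    if not 0.0 <= cutoff < 1.0:
        raise ValueError("cutoff must lie in [0, 1)")
    if mode not in ("max", "mean"):
        raise ValueError("mode must be 'max' or 'mean'")
    stat = table.values.max(axis=1) if mode == "max" else table.values.mean(axis=1)
    keep = stat >= cutoff
    if not keep.any():
        raise ValueError(f"abundance cutoff {cutoff} removes every taxon")
    return AbundanceTable(table.values.loc[keep], unit="proportions")


def generalized_fold_change(
    x,
    y,
    quantiles=DEFAULT_QUANTILES,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Mean difference of matched quantiles of log10(abundance + pseudocount).

    Positive values mean enrichment in ``x``; exactly antisymmetric under
    group exchange.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    q = np.asarray(quantiles, dtype=float)
    if q.size == 0:
        raise ValueError("quantile grid must be non-empty")
    qx = np.quantile(np.log10(x + pseudocount), q)
    qy = np.quantile(np.log10(y + pseudocount), q)
    return float(np.mean(qx - qy))


class AssociationTest(BaseEstimator):
    """Toxicity-vs-no-toxicity differential abundance at one taxonomic level.

    Parameters
    ----------
    cutoff : float
        Max-relative-abundance filter applied before testing (default 0.01).
    quantiles, pseudocount :
        Generalized fold-change grid and offset.
    level : str
        Label recorded in the results (``species``/``genus``/``family``).
    filter_mode : str
        ``'max'`` (default) or ``'mean'`` abundance filter.

    Fitted attributes: ``results_`` (per-taxon DataFrame sorted by q then
    |gFC| descending) and ``n_tested_``.
    """

    def __init__(
        self,
        cutoff: float = 0.01,
        quantiles=DEFAULT_QUANTILES,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        level: str = "species",
        filter_mode: str = "max",
    ):
        self.cutoff = cutoff
        self.quantiles = quantiles
        self.pseudocount = pseudocount
        self.level = level
        self.filter_mode = filter_mode

    def fit(self, table: AbundanceTable, y):
        """Test every retained taxon of ``table`` against binary labels ``y``.

        ``y`` is an array of 0/1 toxicity flags aligned with the table's
        samples.
        """
        rel = table if table.unit == "proportions" else table.relative_abundance()
        y = np.asarray(y)
        if y.size != len(rel.sample_ids):
            raise ValueError("labels must align with the table's samples")
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        n_tox = int((y == 1).sum())
        n_notox = int((y == 0).sum())
        if n_tox < 2 or n_notox < 2:
            raise ValueError(
                f"each toxicity group needs >= 2 samples (got {n_tox}/{n_notox})"
            )
        kept = filter_by_abundance(rel, self.cutoff, mode=self.filter_mode)
        vals = kept.values.to_numpy()
        tox = vals[:, y == 1]
        notox = vals[:, y == 0]
        rows = []
        for i, taxon in enumerate(kept.taxon_ids):
            res = wilcoxon_rank_sum(tox[i], notox[i], mode="normal")
            gfc = generalized_fold_change(
                tox[i], notox[i], quantiles=self.quantiles, pseudocount=self.pseudocount
            )
            rows.append(
                {
                    "taxon_id": taxon,
                    "level": self.level,
                    "p_value": res.p_value,
                    "gFC": gfc,
                    "mean_tox": float(tox[i].mean()),
                    "mean_notox": float(notox[i].mean()),
                    "enriched_group": "toxicity" if gfc > 0 else "no_toxicity",
                }
            )
        df = pd.DataFrame(rows)
        df["q_value"] = benjamini_hochberg(df["p_value"].to_numpy())
        df = df.sort_values(
            ["q_value", "gFC"], key=lambda s: s.abs() if s.name == "gFC" else s,
            ascending=[True, False],
        ).reset_index(drop=True)
        self.results_ = df[
            [
                "taxon_id",
                "level",
                "p_value",
                "q_value",
                "gFC",
                "mean_tox",
                "mean_notox",
                "enriched_group",
            ]
        ]
        self.n_tested_ = len(df)
        return self


def associate(
    table: AbundanceTable,
    metadata: CohortMetadata,
    level: str = "species",
    cutoff: float = 0.01,
    quantiles=DEFAULT_QUANTILES,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Differential-abundance results for one level (thin wrapper)."""
    y = metadata.align(table).frame["toxicity"].to_numpy()
    est = AssociationTest(
        cutoff=cutoff, quantiles=quantiles, pseudocount=pseudocount, level=level
    ).fit(table, y)
    return est.results_


@dataclass
class RepresentativeSets:
    """Per-level representative taxa: T toward toxicity, N toward no-toxicity."""

    T: dict = field(default_factory=dict)  # level -> taxon id
    N: dict = field(default_factory=dict)
    provenance: pd.DataFrame | None = None

    def taxa(self, side: str) -> list:
        d = self.T if side == "T" else self.N
        return [(lvl, tax) for lvl, tax in d.items()]


def select_representatives(
    results_by_level: dict, q_threshold: float = 0.05
) -> RepresentativeSets:
    """Pick, per level, the significant taxon with extreme gFC toward each group.

    The max-gFC significant taxon joins T (toxicity side), the min-gFC one
    joins N; a side with no significant taxon at a level contributes nothing
    (with a warning).
    """
    reps = RepresentativeSets()
    prov = []
    for level, df in results_by_level.items():
        sig = df[df["q_value"] < q_threshold]
        tox_side = sig[sig["gFC"] > 0]
        notox_side = sig[sig["gFC"] < 0]
        if len(tox_side):
            best = tox_side.loc[tox_side["gFC"].idxmax()]
            reps.T[level] = best["taxon_id"]
            prov.append({**best.to_dict(), "set": "T"})
        else:
            warnings.warn(
                f"{level}: no significant toxicity-enriched taxon at q<{q_threshold}",
                stacklevel=2,
            )
        if len(notox_side):
            best = notox_side.loc[notox_side["gFC"].idxmin()]
            reps.N[level] = best["taxon_id"]
            prov.append({**best.to_dict(), "set": "N"})
        else:
            warnings.warn(
                f"{level}: no significant no-toxicity-enriched taxon at q<{q_threshold}",
                stacklevel=2,
            )
    overlap = set(reps.T.values()) & set(reps.N.values())
    if overlap:  # cannot happen with signed gFC, but guard the invariant
        raise RuntimeError(f"representative sets overlap: {overlap}")
    reps.provenance = pd.DataFrame(prov) if prov else pd.DataFrame()
    return reps
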