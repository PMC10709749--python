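"""Core in-memory containers for the pipeline.

An :class:`AbundanceTable` is a taxa x samples matrix of sequencing counts or
relative abundances; :class:`CohortMetadata` carries the per-sample clinical
and design covariates of a longitudinal radiotherapy cohort. Both are thin,
validated wrappers around :class:`pandas.DataFrame`, so every downstream stage
can lean on label-aligned pandas semantics. Phylogenies are represented by
:class:`skbio.TreeNode` directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical sampling schedule: before RT, 2 and 5 weeks after RT start,
#: and 1 and 3 months after RT completion.
DEFAULT_TIMEPOINTS = ("prRT", "RT-2w", "RT-5w", "poRT-1m", "poRT-3m")
DEFAULT_TIMEPOINT_DAYS = (0, 14, 35, 86, 146)

METADATA_COLUMNS = (
    "sample_id",
    "patient_id",
    "timepoint",
    "days",
    "toxicity",
    "field",
    "antihormone",
    "age",
)


@dataclass
class AbundanceTable:
    """Taxa x samples abundance matrix.

    Parameters
    ----------
    values
        DataFrame with taxon ids as the index and sample ids as columns.
        Entries are non-negative counts or proportions.
    unit
        Either ``"counts"`` or ``"proportions"``. Proportion tables must have
        columns summing to 1 (tolerance 1e-9).
    """

    values: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "proportions"):
            raise ValueError(f"unit must be 'counts' or 'proportions', got {self.unit!r}")
        v = self.values
        if not isinstance(v, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (taxa x samples)")
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon ids: {dups}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise TypeError("abundance table must be numeric")
        if not np.all(np.isfinite(arr)):
            raise ValueError("abundance table contains non-finite entries")
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative abundance at taxon {v.index[r]!r}, sample {v.columns[c]!r}"
            )
        if self.unit == "proportions":
            # sums may fall below 1 for filtered sub-communities, but never above
            sums = arr.sum(axis=0)
            bad = np.where(sums > 1.0 + 1e-9)[0]
            if bad.size:
                raise ValueError(
                    f"proportion columns must sum to <= 1; sample {v.columns[bad[0]]!r} "
                    f"sums to {sums[bad[0]]!r}"
                )

    @property
    def taxon_ids(self) -> list:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def relative_abundance(self) -> "AbundanceTable":
        """Column-normalize to proportions (each sample sums to 1)."""
        sums = self.values.sum(axis=0)
        zero = sums.index[sums == 0]
        if len(zero):
            raise ValueError(f"sample {zero[0]!r} has zero total abundance")
        out = self.values.div(sums, axis=1)
        return AbundanceTable(out, unit="proportions")

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return AbundanceTable(self.values.loc[:, list(sample_ids)], unit=self.unit)


@dataclass
class CohortMetadata:
    """Per-sample clinical covariates, keyed by sample id.

    ``frame`` holds one row per sample with the columns in
    :data:`METADATA_COLUMNS`; ``timepoint_order`` declares the ordered
    sampling schedule the ``timepoint`` labels are drawn from.
    """

    frame: pd.DataFrame
    timepoint_order: tuple = field(default=DEFAULT_TIMEPOINTS)

    def __post_init__(self) -> None:
        self.timepoint_order = tuple(self.timepoint_order)
        f = self.frame
        missing = [c for c in METADATA_COLUMNS if c not in f.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        if f["sample_id"].duplicated().any():
            dup = f.loc[f["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id: {dup!r}")
        unknown = set(f["timepoint"]) - set(self.timepoint_order)
        if unknown:
            raise ValueError(
                f"unknown timepoint label(s) {sorted(unknown)}; "
                f"declared order is {list(self.timepoint_order)}"
            )
        order = {t: i for i, t in enumerate(self.timepoint_order)}
        for pid, grp in f.groupby("patient_id"):
            srt = grp.sort_values("timepoint", key=lambda s: s.map(order))
            days = srt["days"].to_numpy()
            if np.any(np.diff(days) < 0):
                raise ValueError(
                    f"days decrease across ordered timepoints for patient {pid!r}"
                )
        bad_tox = set(f["toxicity"]) - {0, 1}
        if bad_tox:
            raise ValueError(f"toxicity must be 0/1, found {sorted(bad_tox)}")

    @property
    def sample_ids(self) -> list:
        return self.frame["sample_id"].tolist()

    @property
    def patient_ids(self) -> list:
        return sorted(self.frame["patient_id"].unique().tolist())

    def indexed(self) -> pd.DataFrame:
        """Frame indexed by sample_id (copy)."""
        return self.frame.set_index("sample_id", drop=False)

    def toxicity_of(self, sample_ids) -> np.ndarray:
        idx = self.indexed()
        return idx.loc[list(sample_ids), "toxicity"].to_numpy()

    def align(self, table: AbundanceTable) -> "CohortMetadata":
        """Restrict to the samples present in `table`, in table order."""
        idx = self.indexed()
        missing = [s for s in table.sample_ids if s not in idx.index]
        if missing:
            raise KeyError(f"samples missing from metadata: {missing}")
        return CohortMetadata(
            idx.loc[table.sample_ids].reset_index(drop=True),
            timepoint_order=self.timepoint_order,
        )
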