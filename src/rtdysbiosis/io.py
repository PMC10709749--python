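"""Readers and writers for the pipeline's interchange formats.

Tabular data travel as plain TSV (tab-separated, UTF-8, ``.`` decimal, no
quoting): abundance tables with taxon ids in the first column and sample ids
in the header, metadata with one row per sample, lineage maps with
``species_id / genus / family`` columns. Phylogenies travel as Newick and are
parsed with scikit-bio. Readers validate strictly and reject malformed input
rather than coercing it.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import DEFAULT_TIMEPOINTS, METADATA_COLUMNS, AbundanceTable, CohortMetadata

_FLOAT_FMT = "%.10g"


def read_abundance_tsv(path, unit: str = "counts") -> AbundanceTable:
    """Read a taxa x samples abundance TSV.

    The first column holds taxon ids; the header row holds sample ids.
    Duplicate labels, negative or non-numeric cells raise ``ValueError``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate taxon id(s) {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample id(s) {dup}")
    try:
        num = df.astype(float)
    except ValueError:
        for j, col in enumerate(df.columns):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().nonzero()[0][0]]
                raise ValueError(
                    f"{path}: non-numeric cell at taxon {row!r}, sample {col!r}"
                ) from None
        raise
    arr = num.to_numpy()
    if (arr < 0).any():
        r, c = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"{path}: negative value at taxon {num.index[r]!r}, sample {num.columns[c]!r}"
        )
    if unit == "counts" and np.allclose(arr, np.round(arr)):
        num = num.round().astype(np.int64)
    return AbundanceTable(num, unit=unit)


def write_abundance_tsv(table: AbundanceTable, path) -> None:
    df = table.values.copy()
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_metadata_tsv(path, timepoint_order=DEFAULT_TIMEPOINTS) -> CohortMetadata:
    """Read per-sample metadata; validates columns, labels and uniqueness."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return CohortMetadata(df[list(METADATA_COLUMNS)], timepoint_order=timepoint_order)


def write_metadata_tsv(metadata: CohortMetadata, path) -> None:
    metadata.frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_newick(path) -> TreeNode:
    """Read a rooted Newick tree.

    Missing branch lengths default to 0 (with a warning); duplicate tip
    labels raise ``ValueError``.
    """
    tree = TreeNode.read(str(path), format="newick")
    tips = [t.name for t in tree.tips()]
    seen, dups = set(), set()
    for name in tips:
        if name in seen:
            dups.add(name)
        seen.add(name)
    if dups:
        raise ValueError(f"{path}: duplicate tip label(s) {sorted(dups)}")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise ValueError(f"{path}: negative branch length on {node.name!r}")
    if n_missing:
        warnings.warn(
            f"{path}: {n_missing} branch length(s) missing; defaulted to 0",
            stacklevel=2,
        )
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_lineage_tsv(path) -> pd.DataFrame:
    """Read a species -> (genus, family) lineage map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["species_id", "genus", "family"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: lineage map missing column(s) {missing}")
    if df["species_id"].duplicated().any():
        dup = df.loc[df["species_id"].duplicated(), "species_id"].iloc[0]
        raise ValueError(f"{path}: duplicate species_id {dup!r}")
    if df[required].isna().any().any() or (df[required] == "").any().any():
        raise ValueError(f"{path}: empty lineage labels are not allowed")
    return df[required].set_index("species_id")


def write_lineage_tsv(lineage: pd.DataFrame, path) -> None:
    out = lineage.copy()
    out.index.name = "species_id"
    out.to_csv(path, sep="\t")


def write_distance_tsv(dm, path) -> None:
    """Write a DistanceMatrix as a square TSV with header row/column."""
    df = dm.to_data_frame() if hasattr(dm, "to_data_frame") else pd.DataFrame(dm)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def check_tree_covers_table(tree: TreeNode, table: AbundanceTable) -> None:
    """Raise if any table taxon is absent from the tree's tips."""
    tips = {t.name for t in tree.tips()}
    missing = [t for t in table.taxon_ids if t not in tips]
    if missing:
        raise ValueError(f"taxa absent from tree: {missing[:5]}{'...' if len(missing) > 5 else ''}")
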