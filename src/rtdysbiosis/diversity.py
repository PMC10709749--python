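"""Alpha diversity, depth normalization, generalized UniFrac, and PCoA.

Generalized UniFrac (Chen et al.) interpolates between weighted and
unweighted variants through the exponent ``alpha`` on the branch-wise total
proportion: for branch i with length b_i and descendant-tip proportion
p_i^A in sample A,

    d(A,B) = sum_i b_i (p_i^A + p_i^B)^alpha |p_i^A - p_i^B| / (p_i^A + p_i^B)
             -----------------------------------------------------------------
             sum_i b_i (p_i^A + p_i^B)^alpha

with zero-total branches skipped. ``alpha=1`` is weighted-normalized
UniFrac; ``alpha=0.5`` (the default here, as recommended by the method's
authors) moderates the weight of highly abundant lineages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from sklearn.base import BaseEstimator

from .containers import AbundanceTable

__all__ = [
    "shannon_index",
    "shannon_by_sample",
    "normalize_to_max_depth",
    "rarefy",
    "GeneralizedUniFrac",
    "generalized_unifrac",
    "Ordination",
    "PCoA",
    "pcoa",
]


def shannon_index(proportions, base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i log p_i of one sample's proportions.

    Natural log by default; ``base`` switches the logarithm base. Zero
    proportions contribute nothing.
    """
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {p.sum()!r}")
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def shannon_by_sample(table: AbundanceTable, base: float | None = None) -> pd.Series:
    """Shannon index for every sample of a proportion table."""
    rel = table if table.unit == "proportions" else table.relative_abundance()
    return pd.Series(
        {s: shannon_index(rel.values[s].to_numpy(), base=base) for s in rel.sample_ids},
        name="shannon",
    )


def normalize_to_max_depth(table: AbundanceTable) -> AbundanceTable:
    """Scale each sample so its total equals the cohort's maximum read count.

    A linear reading of "normalized to the maximal read count": sample s is
    multiplied by max_depth / depth_s, preserving within-sample proportions
    exactly. See :func:`rarefy` for the subsampling alternative.
    """
    if table.unit != "counts":
        raise ValueError("normalize_to_max_depth expects a count table")
    sums = table.values.sum(axis=0)
    zero = sums.index[sums == 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has zero depth")
    scaled = table.values * (float(sums.max()) / sums)
    return AbundanceTable(scaled, unit="counts")


def rarefy(table: AbundanceTable, depth: int | None = None, seed: int = 0) -> AbundanceTable:
    """Subsample every sample without replacement to a common depth.

    ``depth`` defaults to the minimum sample depth. Samples shallower than
    ``depth`` raise.
    """
    if table.unit != "counts":
        raise ValueError("rarefy expects a count table")
    counts = table.values.round().astype(np.int64)
    sums = counts.sum(axis=0)
    if depth is None:
        depth = int(sums.min())
    shallow = sums.index[sums < depth]
    if len(shallow):
        raise ValueError(f"sample {shallow[0]!r} is shallower than depth {depth}")
    rng = np.random.default_rng(seed)
    out = {}
    for s in counts.columns:
        col = counts[s].to_numpy()
        pool = np.repeat(np.arange(col.size), col)
        pick = rng.choice(pool, size=depth, replace=False)
        out[s] = np.bincount(pick, minlength=col.size)
    return AbundanceTable(
        pd.DataFrame(out, index=counts.index), unit="counts"
    )


def _branch_matrix(tree: TreeNode, taxon_ids) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch descendant-tip indicator matrix and branch lengths.

    Returns (B, b) where B is (n_branches x n_taxa) with B[i, t] = 1 if taxon
    t descends through branch i, and b the branch lengths. The root carries
    no branch.
    """
    index = {t: i for i, t in enumerate(taxon_ids)}
    tip_names = {t.name for t in tree.tips()}
    missing = [t for t in taxon_ids if t not in tip_names]
    if missing:
        raise ValueError(f"taxon {missing[0]!r} absent from the tree")
    rows, lengths = [], []
    masks: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            mask = np.zeros(len(taxon_ids))
            if node.name in index:
                mask[index[node.name]] = 1.0
        else:
            mask = np.zeros(len(taxon_ids))
            for child in node.children:
                mask += masks.pop(id(child))
        masks[id(node)] = mask
        if node.parent is not None:
            rows.append(mask)
            lengths.append(float(node.length or 0.0))
    return np.array(rows), np.array(lengths)


class GeneralizedUniFrac(BaseEstimator):
    """Generalized UniFrac distance between samples of a proportion table.

    Parameters
    ----------
    alpha : float in [0, 1]
        Exponent on branch-wise total proportions; 1 recovers
        weighted-normalized UniFrac.
    """

    def __init__(self, alpha: float = 0.5):
        self.alpha = alpha

    def fit(self, tree: TreeNode, y=None):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        self.tree_ = tree
        return self

    def transform(self, table: AbundanceTable) -> DistanceMatrix:
        if not hasattr(self, "tree_"):
            raise RuntimeError("fit(tree) must be called before transform")
        rel = table if table.unit == "proportions" else table.relative_abundance()
        B, b = _branch_matrix(self.tree_, rel.taxon_ids)
        P = B @ rel.values.to_numpy()  # branch x sample descendant proportions
        n = P.shape[1]
        out = np.zeros((n, n))
        for i in range(n):
            pi = P[:, i]
            for j in range(i + 1, n):
                pj = P[:, j]
                tot = pi + pj
                nz = tot > 0
                w = b[nz] * tot[nz] ** self.alpha
                den = w.sum()
                if den == 0:
                    d = 0.0
                else:
                    d = float((w * np.abs(pi[nz] - pj[nz]) / tot[nz]).sum() / den)
                out[i, j] = out[j, i] = d
        return DistanceMatrix(out, ids=rel.sample_ids)

    def fit_transform(self, table: AbundanceTable, tree: TreeNode) -> DistanceMatrix:
        return self.fit(tree).transform(table)


def generalized_unifrac(
    table: AbundanceTable, tree: TreeNode, alpha: float = 0.5
) -> DistanceMatrix:
    """Pairwise generalized UniFrac distances for all samples of ``table``."""
    return GeneralizedUniFrac(alpha=alpha).fit(tree).transform(table)


@dataclass
class Ordination:
    """Classical-scaling (PCoA) result."""

    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # retained (positive), non-increasing
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))
    k_reduced: bool = False


class PCoA(BaseEstimator):
    """Principal coordinates analysis (classical MDS) of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and keeps axes with positive
    eigenvalues; coordinates are eigenvectors scaled by sqrt(eigenvalue).
    If fewer than ``n_components`` positive eigenvalues exist, the result is
    truncated and flagged.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit_transform(self, dm) -> Ordination:
        d = np.asarray(dm.data if hasattr(dm, "data") else dm, dtype=float)
        ids = list(dm.ids) if hasattr(dm, "ids") else list(range(d.shape[0]))
        n = d.shape[0]
        if not 1 <= self.n_components < n:
            raise ValueError("need 1 <= n_components < n_samples")
        d2 = d**2
        j = np.eye(n) - np.ones((n, n)) / n
        g = -0.5 * j @ d2 @ j
        vals, vecs = np.linalg.eigh((g + g.T) / 2.0)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        tol = max(abs(vals[0]), 1.0) * 1e-12
        pos = vals > tol
        neg = vals[vals < -tol]
        k = min(self.n_components, int(pos.sum()))
        reduced = k < self.n_components
        if reduced:
            warnings.warn(
                f"only {k} positive eigenvalue(s); returning {k} axes", stacklevel=2
            )
        if k == 0:  # all-zero distances
            coords = pd.DataFrame(
                np.zeros((n, self.n_components)),
                index=ids,
                columns=[f"PC{i + 1}" for i in range(self.n_components)],
            )
            ord_ = Ordination(coords, np.array([]), np.array([]), neg, True)
        else:
            lam = vals[:k]
            coords = vecs[:, :k] * np.sqrt(lam)
            coords = pd.DataFrame(
                coords, index=ids, columns=[f"PC{i + 1}" for i in range(k)]
            )
            ord_ = Ordination(coords, lam, lam / vals[pos].sum(), neg, reduced)
        self.ordination_ = ord_
        return ord_


def pcoa(dm, n_components: int = 2) -> Ordination:
    """Classical-scaling ordination of a distance matrix."""
    return PCoA(n_components=n_components).fit_transform(dm)
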