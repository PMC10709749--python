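"""Self-contained statistical tests used across the pipeline.

Wilcoxon rank-sum (exact enumeration or tie-corrected normal approximation),
Benjamini-Hochberg step-up q-values, tie-corrected Kruskal-Wallis H, one-way
ANOVA, and pairwise PERMANOVA on a distance matrix. These are implemented
here rather than imported so that every p-value the pipeline reports comes
from one auditable code path; the scipy/statsmodels/scikit-bio equivalents
serve as independent oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import f as f_dist
from scipy.stats import norm, rankdata

DEFAULT_SEED = 20190801

__all__ = [
    "TestResult",
    "PermanovaResult",
    "wilcoxon_rank_sum",
    "benjamini_hochberg",
    "kruskal_wallis",
    "one_way_anova",
    "permanova",
    "permanova_pairwise",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_per_group: tuple

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    group_sizes: tuple
    groups: tuple = ()
    q_value: float | None = None


def _exact_rank_sum_p(ranks_x_sum: float, m: int, n: int) -> float:
    """Two-sided exact p by enumerating all C(m+n, m) rank assignments.

    p = fraction of assignments whose rank sum deviates from its null mean by
    at least as much as observed.
    """
    N = m + n
    mu = m * (N + 1) / 2.0
    obs = abs(ranks_x_sum - mu)
    count = 0
    for assign in combinations(range(1, N + 1), m):
        if abs(sum(assign) - mu) >= obs - 1e-12:
            count += 1
    return count / comb(N, m)


def wilcoxon_rank_sum(x, y, mode: str = "auto", continuity: bool = True) -> TestResult:
    """Two-sided Wilcoxon (Mann-Whitney) rank-sum test.

    mode='exact' enumerates all rank assignments (requires no ties and
    combined n <= 12); mode='normal' uses the tie-corrected normal
    approximation with optional continuity correction; 'auto' picks exact
    when admissible.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    m, n = x.size, y.size
    N = m + n
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:m].sum())
    has_ties = np.unique(pooled).size < N

    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and not has_ties and N <= 12)
    if use_exact:
        if has_ties:
            raise ValueError("exact mode requires tie-free data")
        if N > 12:
            raise ValueError("exact mode limited to combined n <= 12")
        p = _exact_rank_sum_p(w, m, n)
        return TestResult(w, min(p, 1.0), "wilcoxon-exact", (m, n))

    mu = m * (N + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = m * n / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:  # all observations identical
        return TestResult(w, 1.0, "wilcoxon-normal", (m, n))
    dev = w - mu
    if continuity:
        dev = np.sign(dev) * max(abs(dev) - 0.5, 0.0)
    z = dev / np.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return TestResult(w, min(p, 1.0), "wilcoxon-normal", (m, n))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def kruskal_wallis(groups) -> TestResult:
    """Tie-corrected Kruskal-Wallis H test; p from chi-squared with g-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    if correction <= 0:  # every observation identical
        return TestResult(0.0, 1.0, "kruskal-wallis", tuple(g.size for g in groups))
    h /= correction
    h = max(h, 0.0)
    p = float(chi2_dist.sf(h, len(groups) - 1))
    return TestResult(h, p, "kruskal-wallis", tuple(g.size for g in groups))


def one_way_anova(groups) -> TestResult:
    """One-way fixed-effects ANOVA; F = MS_between / MS_within."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    g = len(groups)
    if g < 2:
        raise ValueError("need at least 2 groups")
    if any(grp.size == 0 for grp in groups):
        raise ValueError("all groups must be non-empty")
    n = sum(grp.size for grp in groups)
    if n <= g:
        raise ValueError("residual degrees of freedom must be positive")
    grand = np.concatenate(groups).mean()
    ss_between = sum(grp.size * (grp.mean() - grand) ** 2 for grp in groups)
    ss_within = sum(((grp - grp.mean()) ** 2).sum() for grp in groups)
    sizes = tuple(grp.size for grp in groups)
    if ss_within <= 0:
        if ss_between <= 1e-300:  # all values identical: conventional null
            return TestResult(0.0, 1.0, "anova", sizes)
        return TestResult(np.inf, 0.0, "anova", sizes)
    f = (ss_between / (g - 1)) / (ss_within / (n - g))
    p = float(f_dist.sf(f, g - 1, n - g))
    return TestResult(float(f), p, "anova", sizes)


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """PERMANOVA pseudo-F from squared distances and integer labels."""
    n = d2.shape[0]
    uniq = np.unique(labels)
    g = uniq.size
    ss_total = d2.sum() / (2.0 * n)  # full matrix double-counts pairs
    ss_within = 0.0
    for u in uniq:
        mask = labels == u
        n_g = int(mask.sum())
        ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * n_g)
    return ((ss_total - ss_within) / (g - 1)) / (ss_within / (n - g))


def permanova(
    dm,
    labels,
    n_permutations: int = 999,
    seed: int = DEFAULT_SEED,
    strata=None,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    p = (1 + #{permuted F >= observed F}) / (n_permutations + 1). When
    ``strata`` is given, labels are permuted only within strata (e.g. within
    patient).
    """
    d = np.asarray(dm.data if hasattr(dm, "data") else dm, dtype=float)
    labels = np.asarray(labels)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if labels.size != n:
        raise ValueError("labels length must match the distance matrix")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        small = uniq[counts < 2][0]
        raise ValueError(f"group {small!r} has fewer than 2 samples")
    d2 = d**2
    f_obs = _pseudo_f(d2, labels)
    rng = np.random.default_rng(seed)
    count = 0
    idx = np.arange(n)
    strata = None if strata is None else np.asarray(strata)
    for _ in range(n_permutations):
        if strata is None:
            perm = rng.permutation(idx)
        else:
            perm = idx.copy()
            for s in np.unique(strata):
                mask = np.where(strata == s)[0]
                perm[mask] = mask[rng.permutation(mask.size)]
        if _pseudo_f(d2, labels[perm]) >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return PermanovaResult(float(f_obs), float(p), n_permutations, tuple(counts.tolist()))


def permanova_pairwise(
    dm,
    labels,
    n_permutations: int = 999,
    seed: int = DEFAULT_SEED,
    strata=None,
) -> list[PermanovaResult]:
    """PERMANOVA for every unordered pair of label groups, BH-corrected.

    Returns one :class:`PermanovaResult` per pair with its BH q-value filled
    in; seeds are derived per pair from ``seed`` for reproducibility.
    """
    d = np.asarray(dm.data if hasattr(dm, "data") else dm, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least two groups")
    results = []
    rng = np.random.default_rng(seed)
    for a, b in combinations(uniq.tolist(), 2):
        mask = (labels == a) | (labels == b)
        sub = d[np.ix_(mask, mask)]
        sub_labels = labels[mask]
        sub_strata = None if strata is None else np.asarray(strata)[mask]
        res = permanova(
            sub,
            sub_labels,
            n_permutations=n_permutations,
            seed=int(rng.integers(2**31 - 1)),
            strata=sub_strata,
        )
        res.groups = (a, b)
        results.append(res)
    qs = benjamini_hochberg([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return results
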