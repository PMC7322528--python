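"""Shared statistical primitives.

Fisher's exact test on 2x2 tables with a Haldane-Anscombe-corrected odds
ratio, Benjamini-Hochberg adjustment, Cohen's D, seeded k-means, Pearson
correlation and two-group location tests. Everything downstream (cross-layer
association, TF activity, chromatin-group and interactome scoring) goes
through these functions so that conventions — two-sided tests, +0.5 zero-cell
correction, pooled-SD Cohen's D — are applied uniformly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable2x2",
    "FisherResult",
    "fisher_2x2",
    "bh_adjust",
    "cohens_d",
    "kmeans_cluster",
    "pearson_r",
    "two_group_test",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for a 2x2 table.

    ``a``: in-class in both source and target; ``b``: in-class source only;
    ``c``: in-class target only; ``d``: neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("negative cell count")
        if sum(cells) == 0:
            raise ValueError("all-zero 2x2 table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    log2_or: float
    p: float


def fisher_2x2(table: ContingencyTable2x2, alternative: str = "two_sided") -> FisherResult:
    """Two-sided Fisher exact test with a cross-product odds ratio.

    The p value is the classic two-sided definition: the sum of
    hypergeometric probabilities of all tables (at fixed margins) no more
    probable than the observed one. The odds ratio is the sample
    cross-product ``(a d)/(b c)``; if any cell is zero, 0.5 is added to all
    four cells first (Haldane-Anscombe), keeping ``log2_or`` finite.
    """
    if alternative != "two_sided":
        raise ValueError("only the two-sided alternative is supported")
    a, b, c, d = table.a, table.b, table.c, table.d
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return FisherResult(odds_ratio=odds, log2_or=math.log2(odds), p=float(min(p, 1.0)))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def cohens_d(x, y) -> float:
    """Standardised mean difference with the pooled-SD denominator.

    ``D = (mean(x) - mean(y)) / s_p`` with
    ``s_p^2 = ((nx-1) sx^2 + (ny-1) sy^2) / (nx + ny - 2)``.
    A zero pooled SD with differing means returns signed infinity; with
    equal means it returns 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per sample")
    diff = x.mean() - y.mean()
    pooled_var = (
        (x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)
    ) / (x.size + y.size - 2)
    if pooled_var == 0:
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return float(diff / math.sqrt(pooled_var))


def kmeans_cluster(
    matrix, k: int, seed: int, n_start: int = 25
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded k-means with ``n_start`` k-means++ restarts.

    Returns ``(assignments, centroids)``; deterministic for fixed
    ``(seed, n_start)`` and every cluster non-empty.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if k < 1 or k > X.shape[0]:
        raise ValueError(f"k={k} out of range for {X.shape[0]} rows")
    if np.any(~np.isfinite(X)):
        raise ValueError("matrix contains missing or non-finite values")
    km = KMeans(n_clusters=k, n_init=n_start, random_state=seed)
    labels = km.fit_predict(X)
    return labels, km.cluster_centers_


def pearson_r(x, y) -> float:
    """Product-moment correlation; requires non-degenerate samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    return float(sps.pearsonr(x, y).statistic)


def two_group_test(x, y, kind: str = "student_t") -> float:
    """Two-sided two-group location test.

    ``student_t`` is the equal-variance pooled t test; ``welch_t`` is
    available for unequal variances. ``wilcoxon_rank_sum`` uses exact
    enumeration for small tie-free samples (both n <= 20) and the
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if kind in ("student_t", "welch_t"):
        if x.size < 2 or y.size < 2:
            raise ValueError("t test needs >= 2 observations per group")
        if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
            return 1.0
        res = sps.ttest_ind(x, y, equal_var=(kind == "student_t"))
        return float(res.pvalue)
    if kind == "wilcoxon_rank_sum":
        if x.size < 1 or y.size < 1:
            raise ValueError("rank-sum test needs >= 1 observation per group")
        pooled = np.concatenate([x, y])
        if np.all(pooled == pooled[0]):
            return 1.0
        no_ties = np.unique(pooled).size == pooled.size
        small = max(x.size, y.size) <= 20
        method = "exact" if (no_ties and small) else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return float(res.pvalue)
    raise ValueError(f"unknown test kind {kind!r}")
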