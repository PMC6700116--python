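"""Shared statistical primitives.

The small-sample Wilcoxon path enumerates the full permutation distribution
of the rank sum (tie-aware, average ranks), which stays exact where scipy's
exact method cannot be used because of ties.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import scipy.stats

EXACT_MAX_N = 8  # both groups at or below this size -> full enumeration


def rank_sum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p by full enumeration of group assignments.

    All C(n1+n2, n1) relabelings of the pooled sample are enumerated; the
    p-value is the fraction whose rank sum deviates from its permutation
    mean at least as much as the observed one.  Ties are handled with
    average ranks, so the null distribution is conditional on the observed
    tie pattern.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    w_obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    dev = abs(w_obs - mu)
    hits = 0
    total = 0
    for idx in combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


def rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p for a single gene.

    Exact enumeration when both groups have <= 8 observations, otherwise
    the tie-corrected normal approximation with continuity correction.
    """
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        return rank_sum_exact_p(x, y)
    return float(
        scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def rank_sum_p_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p-values for genes x cells blocks."""
    n1, n2 = a.shape[1], b.shape[1]
    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        return np.array([rank_sum_exact_p(a[i], b[i]) for i in range(a.shape[0])])
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic", axis=1)
    return np.asarray(res.pvalue, dtype=float)


def bonferroni(p: np.ndarray, n_tests: int | None = None) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    n = n_tests if n_tests is not None else p.size
    return np.minimum(1.0, p * n)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    import statsmodels.stats.multitest as smm

    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = smm.multipletests(p[ok], method="fdr_bh")[1]
    return out
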