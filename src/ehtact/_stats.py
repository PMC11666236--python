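"""Shared statistical helpers: rank-sum tests, exact 2x2 tests, BH adjustment."""

from __future__ import annotations

import numpy as np
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

#: Sample-size bound below which the rank-sum p-value is computed by exact
#: enumeration of the null permutation distribution (no tie correction).
EXACT_RANKSUM_MAX_N = 25


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def rank_sum_test(a: np.ndarray, b: np.ndarray):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) per column.

    Parameters
    ----------
    a, b
        Dense arrays of shape (n_a, G) and (n_b, G); the test is applied
        column-wise. Exact p-values are used when n_a + n_b is small,
        otherwise the tie-corrected normal approximation.

    Returns
    -------
    (statistic, pvalue)
        U statistic of sample ``a`` and two-sided p-value, each length G.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    method = "exact" if (a.shape[0] + b.shape[0] <= EXACT_RANKSUM_MAX_N) else "asymptotic"
    res = st.mannwhitneyu(a, b, axis=0, alternative="two-sided", method=method)
    return np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test with a Haldane-corrected odds ratio.

    Returns (odds_ratio, pvalue). The p-value is the conditional
    (hypergeometric) two-sided probability; the odds ratio is the sample
    odds ratio with 0.5 added to every cell whenever any cell is zero, so it
    is always finite.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    _, p = st.fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel().astype(float)
    if t.min() == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return float(odds), float(p)


def hypergeom_overrep_p(k: int, set_size: int, draw_size: int, universe: int) -> float:
    """P(X >= k) for X ~ Hypergeom(universe, set_size, draw_size)."""
    return float(st.hypergeom.sf(k - 1, universe, set_size, draw_size))


def log2_ratio_of_means(mean_a: np.ndarray, mean_b: np.ndarray,
                        pseudocount: float) -> np.ndarray:
    """log2((mean_a + c) / (mean_b + c)) with a small stabilising pseudocount."""
    return np.log2((np.asarray(mean_a, float) + pseudocount)
                   / (np.asarray(mean_b, float) + pseudocount))
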