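"""Independent brute-force oracles used to check the statistical machinery.

Everything here is computed by direct enumeration or first-principles
arithmetic, never by the code paths under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Sums the probabilities of all tables (with the observed margins) whose
    probability does not exceed the observed one (standard relative slack
    for floating-point ties).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = math.comb(n, c1)
    probs = [math.comb(r1, x) * math.comb(r2, c1 - x) / denom
             for x in range(lo, hi + 1)]
    p_obs = probs[a - lo]
    return min(1.0, sum(p for p in probs if p <= p_obs * (1 + 1e-7)))


def hypergeom_upper_tail_oracle(k: int, set_size: int, draws: int,
                                universe: int) -> float:
    """P(X >= k) by direct summation of hypergeometric terms."""
    denom = math.comb(universe, draws)
    hi = min(set_size, draws)
    return sum(math.comb(set_size, x) * math.comb(universe - set_size, draws - x)
               for x in range(k, hi + 1)) / denom


def mann_whitney_u(x, y) -> float:
    """U statistic of sample x (ties counted half)."""
    return float(sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y))


def rank_sum_permutation_oracle(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating every group relabelling."""
    vals = list(x) + list(y)
    n, nx = len(vals), len(x)
    u_obs = mann_whitney_u(x, y)
    us = []
    for comb in itertools.combinations(range(n), nx):
        in_x = set(comb)
        xa = [vals[i] for i in comb]
        yb = [vals[i] for i in range(n) if i not in in_x]
        us.append(mann_whitney_u(xa, yb))
    us = np.asarray(us)
    p_ge = float((us >= u_obs - 1e-9).mean())
    p_le = float((us <= u_obs + 1e-9).mean())
    return min(1.0, 2.0 * min(p_ge, p_le))


def bh_oracle(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values from first principles."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def atp_rates_oracle(basal: float, oligo: float, rot: float, ecar: float):
    """Hand arithmetic of the ATP partitioning with the printed constants."""
    ocr_atp = basal - oligo
    mito_atp = ocr_atp * 2.0 * 2.75
    mito_per = (basal - rot) * 0.5
    per = ecar * 2.6 * 2.28 * 1.1
    glyco_atp = per - mito_per
    total = mito_atp + glyco_atp
    ratio = mito_atp / glyco_atp if glyco_atp > 0 else float("nan")
    return dict(ocr_atp=ocr_atp, mito_atp=mito_atp, mito_per=mito_per,
                per=per, glyco_atp=glyco_atp, total_atp=total,
                mito_glyco_ratio=ratio)
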