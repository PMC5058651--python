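"""Independent oracles used by the test suite.

The Fisher oracle enumerates all 2x2 tables with fixed margins and sums
hypergeometric probabilities directly — no call into the implementation's
scipy tail function.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def fisher_one_sided_exact(t_alt: int, t_depth: int, n_alt: int, n_depth: int) -> float:
    """Exact-rational one-sided Fisher p-value by table enumeration.

    Enumerates every table with the observed margins whose tumor-alt count
    is >= the observed one and sums exact hypergeometric probabilities.
    """
    N = t_depth + n_depth
    K = t_alt + n_alt
    denom = comb(N, t_depth)
    total = Fraction(0)
    lo = max(0, K - n_depth)
    hi = min(K, t_depth)
    for a in range(max(t_alt, lo), hi + 1):
        total += Fraction(comb(K, a) * comb(N - K, t_depth - a), denom)
    return float(total)


def fisher_grid_max_abs_diff(max_total: int, pvalue_fn) -> tuple[float, int]:
    """Compare ``pvalue_fn`` against brute-force enumeration over every 2x2
    table with total depth <= ``max_total``.

    The oracle computes, per margin set (N, K, tumor depth), the full
    hypergeometric pmf from a log-factorial table and reverse-cumsums it —
    an explicit enumeration of all tables with those margins. Returns
    (max absolute p-value difference, number of tables compared).
    """
    lf = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, max_total + 1)))])

    max_diff = 0.0
    n_tables = 0
    for N in range(2, max_total + 1):
        for t_depth in range(1, N):
            n_depth = N - t_depth
            Ks = np.arange(N + 1)
            lo = np.maximum(0, Ks - n_depth)
            hi = np.minimum(Ks, t_depth)
            counts = hi - lo + 1
            offsets = np.concatenate([[0], np.cumsum(counts)])
            total = offsets[-1]
            K_rep = np.repeat(Ks, counts)
            a = (
                np.arange(total)
                - np.repeat(offsets[:-1], counts)
                + np.repeat(lo, counts)
            )
            logpmf = (
                lf[K_rep] - lf[a] - lf[K_rep - a]
                + lf[N - K_rep] - lf[t_depth - a] - lf[N - K_rep - (t_depth - a)]
                - (lf[N] - lf[t_depth] - lf[n_depth])
            )
            pmf = np.exp(logpmf)
            c = np.cumsum(pmf)
            ends = offsets[1:] - 1
            tails = c[np.repeat(ends, counts)] - c + pmf

            p_impl = pvalue_fn(a, t_depth, K_rep - a, n_depth)
            max_diff = max(max_diff, float(np.max(np.abs(p_impl - tails))))
            n_tables += int(total)
    return max_diff, n_tables
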