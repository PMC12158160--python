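"""Independent brute-force oracles used to verify the statistical engines.

These deliberately avoid the code paths (and, where possible, the libraries)
they check: exact integer combinatorics for the hypergeometric tail, the
textbook step-up recursion for Benjamini-Hochberg, and a position-by-position
ECDF enumeration for the running-sum enrichment score.
"""

from __future__ import annotations

from math import comb

import numpy as np


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by exact integer sums."""
    m = min(n, K)
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, m + 1))
    return num / comb(N, n)


def bh_stepup(pvalues) -> np.ndarray:
    """Textbook BH step-up: sort, scale by m/rank, enforce the monotone
    minimum from the largest rank down, clip at 1, restore input order."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def ks_signed(mask) -> float:
    """Signed two-sample KS statistic between member and non-member positions:
    the value of F_in(i) - F_out(i) at its position of maximal magnitude,
    enumerated position by position."""
    mask = np.asarray(mask, dtype=bool)
    n_in = int(mask.sum())
    n_out = mask.size - n_in
    best = 0.0
    cin = cout = 0
    for hit in mask:
        if hit:
            cin += 1
        else:
            cout += 1
        d = cin / n_in - cout / n_out
        if abs(d) > abs(best):
            best = d
    return best
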