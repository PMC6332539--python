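"""Small exact-statistics helpers shared across modules.

Hypergeometric tails and two-sided Fisher p-values are computed with exact
integer arithmetic when the population is small, so results agree with
fixed-margin enumeration to floating-point rounding; large populations fall
back to scipy's log-gamma implementation.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
from scipy import stats

# population size up to which exact big-integer arithmetic is used
_EXACT_N_MAX = 2000


def hypergeom_sf_inclusive(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    Exact (big-integer) for N <= 2000, otherwise scipy's survival function.
    """
    if min(N, K, n, k) < 0 or K > N or n > N:
        raise ValueError("invalid hypergeometric parameters")
    if k <= max(0, n + K - N):
        return 1.0
    if k > min(K, n):
        return 0.0
    if N <= _EXACT_N_MAX:
        total = comb(N, n)
        num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
        return float(Fraction(num, total))
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table by fixed-margin enumeration.

    Sums hypergeometric point probabilities no larger than the observed
    table's. Comparisons are exact integer comparisons of the unnormalized
    weights C(r1, k) * C(r2, c1 - k), so ties are handled without a
    floating-point tolerance.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be a 2x2 array of nonnegative counts")
    a = int(t[0, 0])
    r1 = int(t[0, 0] + t[0, 1])
    r2 = int(t[1, 0] + t[1, 1])
    c1 = int(t[0, 0] + t[1, 0])
    N = r1 + r2
    if N == 0:
        return 1.0
    if N > _EXACT_N_MAX:
        return float(stats.fisher_exact(t)[1])
    lo, hi = max(0, c1 - r2), min(r1, c1)
    w_obs = comb(r1, a) * comb(r2, c1 - a)
    num = sum(
        w_k
        for k in range(lo, hi + 1)
        if (w_k := comb(r1, k) * comb(r2, c1 - k)) <= w_obs
    )
    return float(Fraction(num, comb(N, c1)))


def pearson_with_p(x, y):
    """Pearson product-moment correlation and two-tailed p-value.

    p is computed from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of
    freedom. ``|r| -> 1`` yields p -> 0 without numerical failure. Returns
    ``(nan, nan)`` when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.dot(xc, xc))
    sy = np.sqrt(np.dot(yc, yc))
    if sx == 0.0 or sy == 0.0:
        return float("nan"), float("nan")
    r = float(np.dot(xc, yc) / (sx * sy))
    r = min(1.0, max(-1.0, r))
    df = n - 2
    denom = 1.0 - r * r
    if denom <= 0.0:
        return r, 0.0
    tstat = abs(r) * np.sqrt(df / denom)
    p = 2.0 * float(stats.t.sf(tstat, df))
    return r, min(1.0, p)


def bh_adjust(p):
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
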