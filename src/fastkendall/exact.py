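"""Exact null distribution of the Kendall statistic (no ties).

Under the null of independence with no ties, the number of discordant
pairs of a random permutation of n items — equivalently its inversion
count, and by symmetry the concordant count T — follows the
distribution with counts

    w(n, k) = sum_{i=0}^{n-1} w(n-1, k - i),    w(1, 0) = 1,

for k in [0, u], u = n(n-1)/2. Summing w over k gives n!, so the CDF is
obtained by normalizing with Gamma(n+1). Counts are stored as doubles:
exactness is lost once n! exceeds 2^53 (n >= 19 loses the last digits
of individual counts but CDF ratios remain accurate to ~1e-15), and the
recursion should not be pushed toward n ≈ 170 where n! overflows; the
inference layer caps the exact path far below that.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["NullTable", "ckendall", "pkendall", "gammafn"]


class NullTable:
    """Memoization table for :func:`ckendall`, sized for a given n.

    Entries hold w(n', k) for 1 <= n' <= n_max, k in [0, u(n_max)];
    -1.0 marks "not yet computed". A table may be reused across calls
    at the same (or smaller) n; filling order does not affect values.
    """

    def __init__(self, n_max: int):
        if n_max < 1:
            raise ValueError("n_max must be >= 1")
        self.n_max = int(n_max)
        u = self.n_max * (self.n_max - 1) // 2
        self._w = np.full((self.n_max + 1, u + 1), -1.0)

    def max_statistic(self, n: int) -> int:
        return n * (n - 1) // 2


def ckendall(k: int, n: int, table: NullTable | None = None) -> float:
    """Number of permutations of n items with inversion statistic k.

    Out-of-range k (k < 0 or k > n(n-1)/2) returns 0. Results are
    memoized in ``table`` (allocated per call when omitted); repeated
    calls return identical values regardless of call order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if table is None:
        table = NullTable(n)
    elif n > table.n_max:
        raise ValueError(f"table sized for n_max={table.n_max}, got n={n}")
    return _ckendall(int(k), int(n), table._w)


def _ckendall(k: int, n: int, w: np.ndarray) -> float:
    u = n * (n - 1) // 2
    if k < 0 or k > u:
        return 0.0
    if w[n, k] < 0.0:
        if n == 1:
            w[n, k] = 1.0
        else:
            s = 0.0
            for i in range(n):
                s += _ckendall(k - i, n - 1, w)
            w[n, k] = s
    return float(w[n, k])


def gammafn(x: float) -> float:
    """Gamma function.

    Delegates to the platform's double-precision gamma, which satisfies
    gammafn(n+1) = n! exactly for integer n within double range and
    handles negative non-integer arguments via the reflection formula.
    Poles at nonpositive integers raise :class:`ValueError`.
    """
    return math.gamma(x)


def pkendall(q, n: int, table: NullTable | None = None):
    """CDF of the exact Kendall statistic: P(T <= floor(q)).

    ``q`` may be a scalar or a sequence; the return matches (float or
    ndarray). q < 0 yields 0 and q >= u = n(n-1)/2 yields 1. The sum of
    counts up to floor(q) is normalized by Gamma(n+1) = n!.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if table is None:
        table = NullTable(n)
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    u = n * (n - 1) // 2
    n_fact = gammafn(n + 1)
    out = np.empty(q_arr.shape, dtype=float)
    for idx, qv in np.ndenumerate(q_arr):
        kq = math.floor(qv)
        if kq < 0:
            out[idx] = 0.0
        elif kq >= u:
            out[idx] = 1.0
        else:
            total = 0.0
            for k in range(kq + 1):
                total += _ckendall(k, n, table._w)
            out[idx] = total / n_fact
    if np.isscalar(q) or np.asarray(q).ndim == 0:
        return float(out[0])
    return out
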