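"""Kendall tau-b: Knight's O(n log n) estimator and the O(n²) oracle.

For paired observations (x_i, y_i), i = 1..n, every unordered pair of
observations is concordant, discordant, tied in x only, tied in y only,
or tied in both. With m = n(n-1)/2 total pairs, c concordant and d
discordant, the tie-corrected coefficient is

    tau_b = (c - d) / sqrt((m - Tx) (m - Ty)),

where Tx and Ty count pairs tied in x and in y (joint ties included in
both). With no ties this reduces to (c - d)/m = 4c/(n(n-1)) - 1.

Knight's algorithm avoids the O(n²) pair scan: sort observations by
(x, then y), count tie pairs, then count inversions of the y sequence
with a merge sort. Because x-tied blocks are pre-sorted by y, inversions
come only from pairs with distinct x, and equal-y comparisons never
count, so the swap count is exactly d. The numerator is recovered as

    S = c - d = (m - Tx - Ty + Txy) - 2·swaps,

since m - Tx - Ty + Txy is the number of pairs tied in neither variable,
i.e. c + d.

``oracle_counts``/``oracle_tau`` implement the definitional double-loop
scan and serve as the correctness anchor for the fast path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._sorting import count_tie_pairs, merge_sort_count
from .errors import DimensionError, InsufficientDataError, ZeroVarianceError

__all__ = [
    "PairedSample",
    "ConcordanceCounts",
    "TieSummary",
    "TauResult",
    "knight_tau",
    "oracle_counts",
    "oracle_tau",
]


@dataclass(frozen=True)
class PairedSample:
    """Two equal-length numeric vectors with no missing values.

    Validation (length match, NaN removal, variance checks) happens in
    :func:`fastkendall.validate.check_data`; this container assumes it.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1:
            raise DimensionError("x and y must be one-dimensional vectors")
        if x.shape[0] != y.shape[0]:
            raise DimensionError(
                f"x and y must have equal length (got {x.shape[0]} and {y.shape[0]})"
            )
        if x.shape[0] < 2:
            raise InsufficientDataError("need at least two paired observations")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.x.shape[0]


@dataclass(frozen=True)
class ConcordanceCounts:
    """Pair classification from the definitional O(n²) scan."""

    c: int  # concordant
    d: int  # discordant
    e: int  # tied in x only
    f: int  # tied in y only
    joint: int  # tied in both

    @property
    def total(self) -> int:
        return self.c + self.d + self.e + self.f + self.joint


@dataclass(frozen=True)
class TieSummary:
    """Tie-pair counts and the merge-sort swap count for one sample.

    ``tie_pairs_x``/``tie_pairs_y`` include jointly tied pairs;
    ``swaps`` is the y-inversion count after the (x, y) sort, i.e. the
    number of discordant pairs.
    """

    m: int
    tie_pairs_x: int
    tie_pairs_y: int
    tie_pairs_joint: int
    swaps: int

    @property
    def has_ties(self) -> bool:
        return self.tie_pairs_x > 0 or self.tie_pairs_y > 0

    @property
    def numerator(self) -> int:
        """S = c - d, the tau-b numerator."""
        return (
            self.m
            - self.tie_pairs_x
            - self.tie_pairs_y
            + self.tie_pairs_joint
            - 2 * self.swaps
        )


@dataclass(frozen=True)
class TauResult:
    tau: float
    n: int
    ties: TieSummary


def knight_tau(sample: PairedSample) -> TauResult:
    """Kendall tau-b via sort-and-count-inversions, O(n log n).

    Steps: (1) sort observations by x, breaking x-ties by y, carrying y
    along; (2) count tie pairs in x, in y, and jointly; (3) count
    inversions of the rearranged y with a merge sort; (4) assemble the
    numerator S = m - Tx - Ty + Txy - 2·swaps and divide by
    sqrt((m - Tx)(m - Ty)).

    Raises :class:`ZeroVarianceError` if either variable is constant
    (denominator zero). Ties are defined by exact floating-point
    equality; callers needing a tolerance must pre-round.
    """
    if not isinstance(sample, PairedSample):
        sample = PairedSample(*sample)
    x, y = sample.x, sample.y
    n = sample.n
    m = n * (n - 1) // 2

    order = np.lexsort((y, x))
    xs = x[order]
    ys = y[order]

    tie_x = count_tie_pairs(xs)
    tie_joint = _joint_tie_pairs(xs, ys)
    ys_sorted, swaps = merge_sort_count(ys.tolist())
    tie_y = count_tie_pairs(ys_sorted)

    if tie_x == m or tie_y == m:
        raise ZeroVarianceError(
            "tau is undefined: all pairs are tied in one variable (zero variance)"
        )

    s = m - tie_x - tie_y + tie_joint - 2 * swaps
    # sqrt of the exact integer product keeps tau = ±1 exact for
    # perfectly (anti)monotone data
    tau = s / math.sqrt((m - tie_x) * (m - tie_y))
    tau = max(-1.0, min(1.0, tau))
    ties = TieSummary(
        m=m,
        tie_pairs_x=tie_x,
        tie_pairs_y=tie_y,
        tie_pairs_joint=tie_joint,
        swaps=swaps,
    )
    return TauResult(tau=tau, n=n, ties=ties)


def _joint_tie_pairs(xs: np.ndarray, ys: np.ndarray) -> int:
    """Pairs tied in both variables; input sorted by (x, y)."""
    if xs.shape[0] < 2:
        return 0
    new_run = (xs[1:] != xs[:-1]) | (ys[1:] != ys[:-1])
    run_ids = np.concatenate(([0], np.cumsum(new_run)))
    _, counts = np.unique(run_ids, return_counts=True)
    return int(np.sum(counts * (counts - 1) // 2))


def oracle_counts(sample: PairedSample) -> ConcordanceCounts:
    """Definitional pair classification by a full O(n²) scan.

    Classifies every unordered pair by the sign of
    (x_i - x_j)(y_i - y_j) and the tie pattern. Intentionally naive:
    this is the oracle the fast path is tested against.
    """
    if not isinstance(sample, PairedSample):
        sample = PairedSample(*sample)
    x, y = sample.x, sample.y
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(sample.n, k=1)
    sx = sx[iu]
    sy = sy[iu]
    prod = sx * sy
    c = int(np.count_nonzero(prod > 0))
    d = int(np.count_nonzero(prod < 0))
    e = int(np.count_nonzero((sx == 0) & (sy != 0)))
    f = int(np.count_nonzero((sx != 0) & (sy == 0)))
    joint = int(np.count_nonzero((sx == 0) & (sy == 0)))
    return ConcordanceCounts(c=c, d=d, e=e, f=f, joint=joint)


def oracle_tau(sample: PairedSample) -> float:
    """Definitional tau-b: (c-d)/sqrt((c+d+e)(c+d+f)).

    ``e``/``f`` are pairs tied in exactly one variable, so
    c+d+e = m - (Ty incl. joint) and c+d+f = m - (Tx incl. joint): the
    product equals the Knight denominator (m-Tx)(m-Ty). Raises
    :class:`ZeroVarianceError` when either factor is zero.
    """
    counts = oracle_counts(sample)
    denom_x = counts.c + counts.d + counts.e
    denom_y = counts.c + counts.d + counts.f
    if denom_x == 0 or denom_y == 0:
        raise ZeroVarianceError("tau is undefined: a variable has zero variance")
    return (counts.c - counts.d) / math.sqrt(denom_x * denom_y)
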