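"""Hypothesis tests, confidence intervals, and the pseudo-R² helper.

Two inference paths are provided for H0: tau = 0.

Exact path (valid only without ties): the statistic is T, the number of
concordant pairs, whose null distribution is the exact permutation
distribution from :mod:`fastkendall.exact`. Tail probabilities include
the observed point:

    p_greater = 1 - P(T <= t_obs - 1),   p_less = P(T <= t_obs),
    p_two     = min(2 * min(p_greater, p_less), 1).

Normal-approximation path: the statistic is z = (S - shift)/sqrt(v)
with S = c - d, shift = sign(S) if the continuity correction is on
(else 0), and v the tie-corrected null variance

    v = (v0 - vt - vu)/18 + v1 + v2,
    v0 = n(n-1)(2n+5),
    vt = sum t_i(t_i-1)(2 t_i+5)  over x tie-group sizes t_i,
    vu = analogous over y tie groups,
    v1 = [sum t_i(t_i-1)][sum u_j(u_j-1)] / (2 n (n-1)),
    v2 = [sum t_i(t_i-1)(t_i-2)][sum u_j(u_j-1)(u_j-2)] / (9 n (n-1)(n-2)),

which reduces to n(n-1)(2n+5)/18 with no ties.

Confidence intervals use the normal approximation with
se = sqrt(2(2n+5)/(9 n (n-1))) and the z_{1-alpha/2} quantile for every
alternative; one-sided alternatives pin the other bound at ±1.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import PairedSample, TauResult, knight_tau
from .errors import ExactTestError, InsufficientDataError
from .exact import NullTable, pkendall

__all__ = [
    "Alternative",
    "ExactMode",
    "TestSpec",
    "TestResult",
    "kendall_test",
    "confidence_interval",
    "pseudo_r2",
    "EXACT_N_MAX",
]

# Largest n for which exact_mode="auto" uses the permutation null.
EXACT_N_MAX = 50


class Alternative(str, enum.Enum):
    TWO_SIDED = "two-sided"
    GREATER = "greater"
    LESS = "less"


class ExactMode(str, enum.Enum):
    AUTO = "auto"
    FORCE_EXACT = "exact"
    FORCE_APPROX = "approx"


@dataclass(frozen=True)
class TestSpec:
    """Options controlling :func:`kendall_test`.

    ``continuity`` applies the ±1 correction to S on the approximate
    path only; it is off by default.
    """

    __test__ = False  # not a pytest collectible despite the name

    alternative: Alternative = Alternative.TWO_SIDED
    conf_level: float = 0.95
    exact_mode: ExactMode = ExactMode.AUTO
    continuity: bool = False

    def __post_init__(self):
        object.__setattr__(self, "alternative", Alternative(self.alternative))
        object.__setattr__(self, "exact_mode", ExactMode(self.exact_mode))
        if not 0.0 < self.conf_level < 1.0:
            raise ValueError("conf_level must be strictly between 0 and 1")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a Kendall rank-correlation test.

    ``statistic`` is T (concordant pairs) on the exact path and the
    z-score on the approximate path, as indicated by ``statistic_name``.
    """

    __test__ = False  # not a pytest collectible despite the name

    tau: float
    statistic: float
    statistic_name: str
    p_value: float
    ci_low: float
    ci_high: float
    method: str
    alternative: Alternative
    conf_level: float
    n: int

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "statistic": self.statistic,
            "statistic_name": self.statistic_name,
            "p_value": self.p_value,
            "conf_level": self.conf_level,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "method": self.method,
            "alternative": self.alternative.value,
            "n": self.n,
        }

    def render(self, data_label: str = "x and y") -> str:
        """Plain-text report in the conventional R-style layout."""
        alt_text = {
            Alternative.TWO_SIDED: "true tau is not equal to 0",
            Alternative.GREATER: "true tau is greater than 0",
            Alternative.LESS: "true tau is less than 0",
        }[self.alternative]
        pct = self.conf_level * 100
        pct_text = f"{pct:.6g}"
        return (
            "\n\tKendall's rank correlation tau\n\n"
            f"data: {data_label}\n"
            f"tau = {self.tau:.5f}, {self.statistic_name} = {self.statistic:.7g}, "
            f"p-value = {self.p_value:.4g}\n"
            f"alternative hypothesis: {alt_text}\n"
            f"{pct_text} percent confidence interval:\n"
            f" {self.ci_low:.7f} {self.ci_high:.7f}\n"
        )


def kendall_test(
    sample: PairedSample,
    spec: TestSpec | None = None,
    *,
    null_table: NullTable | None = None,
) -> TestResult:
    """Test H0: tau = 0 against the alternative in ``spec``.

    With ``exact_mode="auto"`` the exact permutation null is used when
    the sample has no ties and n < 50; otherwise the tie-corrected
    normal approximation. Forcing the exact path on tied data raises
    :class:`ExactTestError` since the permutation distribution assumes
    distinct ranks. ``null_table`` optionally supplies a reusable
    memoization table for repeated exact tests at the same n.
    """
    if spec is None:
        spec = TestSpec()
    if not isinstance(sample, PairedSample):
        sample = PairedSample(*sample)
    res = knight_tau(sample)
    ties = res.ties
    n = res.n

    if spec.exact_mode is ExactMode.FORCE_EXACT and ties.has_ties:
        raise ExactTestError(
            "exact test requested but the data contain ties; the exact null "
            "distribution assumes no ties (use the normal approximation)"
        )
    use_exact = spec.exact_mode is ExactMode.FORCE_EXACT or (
        spec.exact_mode is ExactMode.AUTO and not ties.has_ties and n < EXACT_N_MAX
    )

    if use_exact:
        statistic, statistic_name, p_value = _exact_test(res, spec, null_table)
        method = "Kendall's rank correlation tau (exact test)"
    else:
        statistic, statistic_name, p_value = _approx_test(sample, res, spec)
        method = "Kendall's rank correlation tau (normal approximation"
        method += ", continuity corrected)" if spec.continuity else ")"

    ci_low, ci_high = confidence_interval(res.tau, n, spec)
    return TestResult(
        tau=res.tau,
        statistic=statistic,
        statistic_name=statistic_name,
        p_value=float(p_value),
        ci_low=ci_low,
        ci_high=ci_high,
        method=method,
        alternative=spec.alternative,
        conf_level=spec.conf_level,
        n=n,
    )


def _exact_test(res: TauResult, spec: TestSpec, table: NullTable | None):
    ties = res.ties
    n = res.n
    # no ties: every pair is concordant or discordant, d equals the swap count
    t_obs = ties.m - ties.swaps
    p_greater = 1.0 - pkendall(t_obs - 1, n, table)
    p_less = pkendall(t_obs, n, table)
    if spec.alternative is Alternative.GREATER:
        p = p_greater
    elif spec.alternative is Alternative.LESS:
        p = p_less
    else:
        p = min(2.0 * min(p_greater, p_less), 1.0)
    return float(t_obs), "T", p


def _approx_test(sample: PairedSample, res: TauResult, spec: TestSpec):
    n = res.n
    s = float(res.ties.numerator)
    v = _null_variance(sample, n)
    shift = math.copysign(1.0, s) if (spec.continuity and s != 0.0) else 0.0
    z = (s - shift) / math.sqrt(v)
    if spec.alternative is Alternative.GREATER:
        p = stats.norm.sf(z)
    elif spec.alternative is Alternative.LESS:
        p = stats.norm.cdf(z)
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    return float(z), "z", min(float(p), 1.0)


def _null_variance(sample: PairedSample, n: int) -> float:
    """Tie-corrected variance of S = c - d under independence."""
    _, tx = np.unique(sample.x, return_counts=True)
    _, ty = np.unique(sample.y, return_counts=True)
    tx = tx.astype(float)
    ty = ty.astype(float)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = float(np.sum(tx * (tx - 1) * (2 * tx + 5)))
    vu = float(np.sum(ty * (ty - 1) * (2 * ty + 5)))
    v = (v0 - vt - vu) / 18.0
    if n > 2:
        v += (
            np.sum(tx * (tx - 1) * (tx - 2))
            * np.sum(ty * (ty - 1) * (ty - 2))
            / (9.0 * n * (n - 1) * (n - 2))
        )
    v += np.sum(tx * (tx - 1)) * np.sum(ty * (ty - 1)) / (2.0 * n * (n - 1))
    return float(v)


def confidence_interval(
    tau: float, n: int, spec: TestSpec | None = None
) -> tuple[float, float]:
    """Normal-approximation CI for tau at ``spec.conf_level``.

    Uses se = sqrt(2(2n+5)/(9n(n-1))) and the z_{1-alpha/2} quantile
    for every alternative; for one-sided alternatives the unbounded
    side is pinned at +1 or -1. Bounds are clamped to [-1, 1].
    """
    if spec is None:
        spec = TestSpec()
    if n < 3:
        raise InsufficientDataError("confidence interval requires n >= 3")
    se = math.sqrt(2.0 * (2 * n + 5) / (9.0 * n * (n - 1)))
    zq = float(stats.norm.ppf(1.0 - (1.0 - spec.conf_level) / 2.0))
    if spec.alternative is Alternative.GREATER:
        low, high = tau - zq * se, 1.0
    elif spec.alternative is Alternative.LESS:
        low, high = -1.0, tau + zq * se
    else:
        low, high = tau - zq * se, tau + zq * se
    return max(low, -1.0), min(high, 1.0)


def pseudo_r2(observed, fitted) -> float:
    """Squared Kendall correlation between observed and fitted values.

    A goodness-of-fit summary for count-data regressions (e.g. Poisson
    models with fixed effects) where a conventional R² is unavailable.
    Always in [0, 1]; an anti-monotone fit also scores positively.
    """
    from .validate import check_data

    sample = check_data(observed, fitted)
    return knight_tau(sample).tau ** 2
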