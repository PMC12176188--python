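"""Synthetic bivariate samples with known population tau.

Draws (x, y) from a bivariate standard normal with latent correlation
rho, for which Greiner's relation gives the population Kendall
correlation exactly:

    tau = (2 / pi) * arcsin(rho).

Optionally, values are rounded to a fixed grid (``tie_granularity``) to
induce ties; discretization perturbs the effective tau slightly, so the
identity above holds exactly only for the continuous sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import PairedSample

__all__ = ["SyntheticSpec", "generate_sample", "tau_from_rho"]


def tau_from_rho(rho: float) -> float:
    """Population Kendall tau of a bivariate normal with correlation rho."""
    return (2.0 / math.pi) * math.asin(rho)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one reproducible synthetic sample.

    ``rho`` is the latent Gaussian correlation, strictly inside (-1, 1);
    ``tie_granularity``, when set, rounds both variables to multiples of
    that grid step to create ties.
    """

    n: int
    rho: float = 0.0
    tie_granularity: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must be strictly inside (-1, 1)")
        if self.tie_granularity is not None and self.tie_granularity <= 0:
            raise ValueError("tie_granularity must be positive")


def generate_sample(spec: SyntheticSpec) -> PairedSample:
    """Draw the sample described by ``spec``; identical seed, identical draw."""
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((2, spec.n))
    x = z[0]
    y = spec.rho * z[0] + math.sqrt(1.0 - spec.rho**2) * z[1]
    if spec.tie_granularity is not None:
        g = spec.tie_granularity
        x = np.round(x / g) * g
        y = np.round(y / g) * g
    return PairedSample(x, y)
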