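"""fastkendall: O(n log n) Kendall rank correlation with exact inference.

Computes the tie-corrected Kendall coefficient (tau-b) by Knight's
sort-and-count-inversions algorithm, provides the exact small-sample
null distribution of the concordant-pair statistic, normal-approximation
tests and confidence intervals, and a pseudo-R² helper for count-data
regressions.
"""

from .core import (
    ConcordanceCounts,
    PairedSample,
    TauResult,
    TieSummary,
    knight_tau,
    oracle_counts,
    oracle_tau,
)
from .errors import (
    DimensionError,
    ExactTestError,
    FastKendallError,
    InsufficientDataError,
    ZeroVarianceError,
)
from .exact import NullTable, ckendall, gammafn, pkendall
from .inference import (
    Alternative,
    ExactMode,
    TestResult,
    TestSpec,
    confidence_interval,
    kendall_test,
    pseudo_r2,
)
from .simulate import SyntheticSpec, generate_sample, tau_from_rho
from .validate import check_data, read_paired, tau_matrix

__version__ = "0.1.0"


def kendall_cor(x, y=None) -> float:
    """Kendall tau-b of two paired vectors (validated, O(n log n))."""
    return knight_tau(check_data(x, y)).tau


def kendall_cor_test(x, y=None, **spec_kwargs) -> TestResult:
    """Validate inputs and run :func:`kendall_test`.

    Keyword arguments (``alternative``, ``conf_level``, ``exact_mode``,
    ``continuity``) populate a :class:`TestSpec`.
    """
    return kendall_test(check_data(x, y), TestSpec(**spec_kwargs))


__all__ = [
    "Alternative",
    "ConcordanceCounts",
    "DimensionError",
    "ExactMode",
    "ExactTestError",
    "FastKendallError",
    "InsufficientDataError",
    "NullTable",
    "PairedSample",
    "SyntheticSpec",
    "TauResult",
    "TestResult",
    "TestSpec",
    "TieSummary",
    "ZeroVarianceError",
    "check_data",
    "ckendall",
    "confidence_interval",
    "gammafn",
    "generate_sample",
    "kendall_cor",
    "kendall_cor_test",
    "kendall_test",
    "knight_tau",
    "oracle_counts",
    "oracle_tau",
    "pkendall",
    "pseudo_r2",
    "read_paired",
    "tau_from_rho",
    "tau_matrix",
]
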