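"""Exception types raised during validation and estimation."""


class FastKendallError(ValueError):
    """Base class for all package-specific errors."""


class DimensionError(FastKendallError):
    """x and y do not have the same length / compatible shapes."""


class InsufficientDataError(FastKendallError):
    """Fewer than two complete observations remain after cleaning."""


class ZeroVarianceError(FastKendallError):
    """A variable is constant, so the rank correlation is undefined."""


class ExactTestError(FastKendallError):
    """The exact null distribution was requested where it is invalid."""
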