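"""Exception hierarchy shared across the package."""


class BasisBrainError(Exception):
    """Base class for all package-specific errors."""


class GridMismatchError(BasisBrainError):
    """Volumes do not share the grid shape/affine of the mask."""


class InvalidMaskError(BasisBrainError):
    """Mask is empty or otherwise unusable."""


class DimensionError(BasisBrainError):
    """Array dimensions are inconsistent with the operation's contract."""


class ParameterError(BasisBrainError, ValueError):
    """A scalar parameter is outside its admissible range."""


class DegenerateDataError(BasisBrainError):
    """Data are degenerate for the requested operation (e.g. constant column)."""


class EmptyBasisError(BasisBrainError):
    """A basis construction produced no usable columns."""


class ConditioningError(BasisBrainError):
    """A matrix factorization failed; the system is numerically singular."""


class ConvergenceError(BasisBrainError):
    """An iterative procedure failed to converge after documented retries."""
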