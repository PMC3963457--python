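"""Exception hierarchy shared across the package."""


class DensityTailError(Exception):
    """Base class for all package errors."""


class ModelValidationError(DensityTailError, ValueError):
    """A density model violates its invariants (e.g. non-PD covariance)."""


class DimensionMismatchError(ModelValidationError):
    """Observation matrix dimensionality does not match the model."""


class InsufficientDataError(DensityTailError, ValueError):
    """Too few observations for the requested operation (e.g. tail fit)."""


class FitConvergenceError(DensityTailError, RuntimeError):
    """The likelihood optimiser failed to converge; never silent."""


class DomainError(DensityTailError, ValueError):
    """An argument lies outside the mathematical domain of the function."""


class GridCoverageError(DensityTailError, ValueError):
    """A quadrature grid fails to capture enough of the model's mass."""


class InputFormatError(DensityTailError, ValueError):
    """Malformed input file (ragged CSV row, schema violation, ...)."""
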