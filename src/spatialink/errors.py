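"""Exception types raised across the package."""


class SpatialinkError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SpatialinkError):
    """A dataset or parameter violates an invariant (e.g. negative expression)."""


class AlignmentError(SpatialinkError):
    """Input files disagree on dimensions or cell identifiers."""


class EmptyResultError(SpatialinkError):
    """An operation produced an empty dataset or graph."""


class SamplingError(SpatialinkError):
    """A random sampling request cannot be satisfied (e.g. too few non-edges)."""


class NumericalError(SpatialinkError):
    """Non-finite values encountered during model evaluation or training."""
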