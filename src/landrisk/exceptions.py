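"""Exception hierarchy for landrisk.

All errors derive from :class:`LandriskError` so callers can catch the
package's failures with a single except clause; the subclasses mirror the
distinct failure contracts of the individual operations (bad parameters,
too-little data, numerical non-convergence, shape mismatches, degenerate
statistics, and infeasible synthetic-generation requests).
"""


class LandriskError(ValueError):
    """Base class for all landrisk errors."""


class InvalidParameterError(LandriskError):
    """A model or configuration parameter violates its contract."""


class InsufficientDataError(LandriskError):
    """Too few samples to perform the requested computation."""


class NumericalFailureError(LandriskError):
    """A numerical routine failed to reach the requested tolerance."""

    def __init__(self, message: str, error_estimate: float | None = None):
        super().__init__(message)
        self.error_estimate = error_estimate


class ShapeError(LandriskError):
    """Series lengths or array shapes are inconsistent."""


class PhaseDetectionError(LandriskError):
    """The landing phase could not be located in a trial."""


class DegenerateInputError(LandriskError):
    """Zero-variance / constant input where spread is required."""


class GenerationError(LandriskError):
    """A synthetic-data request is infeasible."""
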