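"""Exception hierarchy shared across the package."""


class VesipoolError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(VesipoolError, ValueError):
    """A configuration or model parameter violates its invariants."""


class InvalidInputError(VesipoolError, ValueError):
    """Input data (stack, ROI, trace) violates a precondition."""


class CorrectionFailureError(VesipoolError):
    """Photobleaching correction produced a nonpositive cell reference."""


class DegenerateBleachError(VesipoolError):
    """No bleach step present: pre-bleach mean <= first post-bleach value."""


class DegenerateNormalizationError(VesipoolError):
    """Traffic normalization denominator is effectively zero."""


class FitFailureError(VesipoolError):
    """Nonlinear fit failed to converge from every start point.

    Carries per-start diagnostics in ``diagnostics``.
    """

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class MissingTimepointError(VesipoolError):
    """No sample lies close enough to the requested query time."""


class InvalidTrackError(VesipoolError, ValueError):
    """A kymograph track violates its invariants (e.g. zero time step)."""
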