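"""Exception hierarchy shared across the package."""


class HcgateError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(HcgateError, ValueError):
    """An argument violates a documented precondition."""


class FitFailureError(HcgateError, RuntimeError):
    """A nonlinear fit failed to converge or is degenerate.

    Carries optional ``fallback`` estimates (e.g. peeling initial values)
    so callers can inspect what the optimiser was working with.
    """

    def __init__(self, message, fallback=None):
        super().__init__(message)
        self.fallback = fallback


class NoRootError(HcgateError, RuntimeError):
    """A bracketed root search found no sign change on the interval."""


class DegenerateSolutionError(HcgateError, RuntimeError):
    """A linear solve has no unique solution (e.g. disconnected chain)."""
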