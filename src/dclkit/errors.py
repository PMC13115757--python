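"""Exception hierarchy shared across dclkit."""


class DclkitError(Exception):
    """Base class for all dclkit errors."""


class DomainError(DclkitError, ValueError):
    """An input is outside the physically meaningful domain."""


class FitError(DclkitError, RuntimeError):
    """A model fit failed to converge or produced an unusable optimum.

    The best iterate reached, when available, is attached as ``best_fit``.
    """

    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


class ValidationError(DclkitError, ValueError):
    """A data file or in-memory container violates its schema invariants."""
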