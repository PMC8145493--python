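"""Exception hierarchy shared across the analysis modules."""


class MycosynergyError(Exception):
    """Base class for all package-specific errors."""


class InvalidControlError(MycosynergyError, ValueError):
    """A control measurement is missing, non-positive, or degenerate."""


class DesignError(MycosynergyError, ValueError):
    """An assay or mixture design violates its structural contract
    (e.g. zero or duplicate control rows, mismatched ladder lengths)."""


class SchemaError(MycosynergyError, ValueError):
    """A CSV file does not conform to the expected schema; the message
    names the offending row and column where possible."""


class InsufficientDataError(MycosynergyError, ValueError):
    """Too few usable dose groups to fit a concentration-mortality model."""


class ConvergenceError(MycosynergyError, RuntimeError):
    """Iterative fitting failed to converge; carries the last iterate."""

    def __init__(self, message, last_fit=None):
        super().__init__(message)
        self.last_fit = last_fit
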