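"""Exception hierarchy for the chamber twin."""


class IHTwinError(Exception):
    """Base class for all package errors."""


class ValidationError(IHTwinError):
    """A configuration value or input record violates its declared bounds.

    The message names the offending field.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class ActuationError(IHTwinError):
    """A valve was asked to deliver a physically impossible flow."""


class StabilityError(IHTwinError):
    """The explicit-Euler step size violates the dilution stability bound Q*dt/V < 1."""
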