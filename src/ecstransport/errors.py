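"""Exception types shared across the package."""


class ECSTransportError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(ECSTransportError, ValueError):
    """A physical parameter is outside its admissible range."""


class DegenerateInputError(ECSTransportError, ValueError):
    """The input is formally valid but carries no usable signal
    (e.g. an unbleached stack offered for recovery analysis)."""


class StabilityError(ECSTransportError, ValueError):
    """An explicit time step violates the numerical stability bound."""
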