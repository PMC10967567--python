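"""Package exception hierarchy."""


class LactofitError(Exception):
    """Base class for all lactofit errors."""


class ConfigurationError(LactofitError):
    """Invalid configuration: unknown model name, infeasible simulation config."""


class DomainError(LactofitError, ValueError):
    """Argument outside the mathematical domain of an operation (e.g. t < 0)."""


class InsufficientData(LactofitError):
    """Too few usable observations for the requested operation."""


class DegenerateLactation(LactofitError):
    """A lactation whose records carry no usable signal (e.g. all yields zero)."""


class NoPeak(DomainError):
    """The fitted curve has no interior maximum (monotone non-declining)."""
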