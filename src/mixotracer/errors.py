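"""Exception hierarchy shared across the package."""


class MixotracerError(Exception):
    """Base class for all package errors."""


class ValidationError(MixotracerError, ValueError):
    """Input data violate a documented precondition or schema."""


class ConfigurationError(MixotracerError, ValueError):
    """A configuration object is internally inconsistent; names the field."""


class UndefinedMixingError(MixotracerError, ArithmeticError):
    """Endmember separation too small for a stable two-source mixing model."""


class ComputationError(MixotracerError, RuntimeError):
    """A pipeline stage failed after inputs validated."""
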