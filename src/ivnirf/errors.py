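"""Exception and warning taxonomy shared across the package."""


class IvnirfError(Exception):
    """Base class for all package errors."""


class DomainError(IvnirfError, ValueError):
    """An input violates a documented precondition (negative distance, ...)."""


class FitError(IvnirfError, RuntimeError):
    """A model fit cannot be performed (too few usable points)."""


class SchemaError(IvnirfError, ValueError):
    """A serialized container does not conform to the expected layout."""


class ConfigError(IvnirfError, ValueError):
    """An invalid run configuration (unknown key, missing required value)."""


class MissingGuidewireError(IvnirfError, ValueError):
    """A frame contains no guidewire-labeled samples usable as reference."""


class IvnirfWarning(UserWarning):
    """Base warning category."""


class SuperUnityTransmissionWarning(IvnirfWarning):
    """Measured reference intensity exceeds the calibrated incident intensity."""


class NegativeCoefficientWarning(IvnirfWarning):
    """An estimated attenuation coefficient came out negative (noise)."""
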