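"""Exception hierarchy for the tobaccopolicy package."""


class TobaccoPolicyError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TobaccoPolicyError, ValueError):
    """An invalid generator or run configuration; names the offending field."""


class SchemaError(TobaccoPolicyError, ValueError):
    """An input table does not match the documented column schema."""


class DomainError(TobaccoPolicyError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class EmptyInputError(TobaccoPolicyError, ValueError):
    """An operation received no usable rows."""


class AlignmentError(TobaccoPolicyError, ValueError):
    """Two keyed inputs could not be aligned on their shared keys."""


class FitError(TobaccoPolicyError, RuntimeError):
    """Model estimation failed structurally (singular design, too few groups)."""


class MethodError(TobaccoPolicyError, ValueError):
    """An operation was requested with an incompatible estimation method."""


class GenerationError(TobaccoPolicyError, RuntimeError):
    """Synthetic data generation produced invalid values."""
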