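"""Exception hierarchy shared across the package."""


class SepsistypesError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SepsistypesError, ValueError):
    """An argument or configuration value is out of its valid range."""


class FormatError(SepsistypesError, ValueError):
    """An input file does not conform to its expected text format."""


class DegenerateInputError(SepsistypesError, ValueError):
    """The input is structurally valid but leaves nothing to operate on."""


class MissingValuesError(SepsistypesError, ValueError):
    """An operation that requires a complete matrix received missing values."""


class PipelineError(SepsistypesError, RuntimeError):
    """A multi-stage analysis could not proceed past one of its stages."""
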