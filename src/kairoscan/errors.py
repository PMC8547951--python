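"""Exception hierarchy; exit codes are consumed by the CLI."""


class KairoscanError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(KairoscanError):
    """Invalid configuration (simulation or pipeline)."""

    exit_code = 2


class InputError(KairoscanError):
    """Invalid or missing input data."""

    exit_code = 3


class ParseError(InputError):
    """A file could not be parsed; message names the offending line."""


class ValidationError(InputError):
    """Parsed data violates a structural invariant."""


class ComputationError(KairoscanError):
    """A statistical or numerical step could not be carried out."""

    exit_code = 4
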