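"""Exception hierarchy shared across the pipeline."""


class MedipmarkError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MedipmarkError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class InputError(MedipmarkError, ValueError):
    """Malformed or inconsistent input data (CLI exit code 2)."""


class StageError(MedipmarkError, RuntimeError):
    """A pipeline stage failed (CLI exit code 3); the message names the stage."""
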