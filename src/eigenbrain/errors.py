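"""Exception hierarchy for the eigenbrain pipeline."""


class EigenbrainError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(EigenbrainError, ValueError):
    """Invalid configuration values (shapes, counts, bounds)."""


class DataError(EigenbrainError, ValueError):
    """Malformed or inconsistent input data."""


class SingleClassError(DataError):
    """An operation requiring both classes received only one."""


class DegenerateInputError(EigenbrainError, ValueError):
    """Numerically degenerate input (all-zero profile, zero variance, ...)."""


class SelectionError(EigenbrainError, RuntimeError):
    """No candidate satisfied the selection rule.

    Carries the full diagnostic result so callers can inspect why.
    """

    def __init__(self, message, result=None):
        super().__init__(message)
        self.result = result


class StageError(EigenbrainError, RuntimeError):
    """A pipeline stage failed; wraps the original error with the stage name."""

    def __init__(self, stage, original):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original
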