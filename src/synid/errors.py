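"""Exception hierarchy shared across the package.

Exit-code mapping used by the command-line layer:
ConfigurationError -> 2, DependencyError -> 3, DataError (and subclasses) -> 4.
"""


class SynidError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SynidError):
    """Invalid configuration value (bad filter band, non-integer rate ratio, ...)."""


class DataError(SynidError):
    """Invalid or degenerate input data."""


class DependencyError(SynidError):
    """A required upstream artifact is missing or inconsistent."""


class TrainingError(DataError):
    """Classifier training cannot proceed (e.g. too few samples for a direction)."""


class TrialExcludedError(DataError):
    """A trial cannot be decoded and must be excluded from the analysis."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason
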