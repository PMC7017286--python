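"""Exception hierarchy for the equichip pipeline."""


class EquichipError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EquichipError):
    """A configuration value is invalid (e.g. zero-length chromosome)."""


class PlacementError(EquichipError):
    """Requested regulatory elements do not fit in the genome."""


class LookupError_(EquichipError):
    """Unknown tissue or mark requested from a truth set."""


class UndefinedMetricError(EquichipError):
    """A QC metric is undefined for the given input (e.g. empty library)."""


class NoSignalError(EquichipError):
    """Cross-correlation requested but one strand carries no tags."""


class IncompleteReportError(EquichipError):
    """A QC verdict was requested with one or more metrics missing."""


class ValidationError(EquichipError):
    """Input records violate a structural contract (bounds, labels, ranges)."""


class ParseError(EquichipError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class DependencyError(EquichipError):
    """A pipeline stage is missing an upstream artifact."""
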