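"""Exception hierarchy for the panelcnv pipeline.

Every pipeline-specific failure derives from :class:`PanelCNVError` so that
callers (and the CLI) can distinguish bad input (exit code 3) from QC
failures (exit code 2) and from programming errors.
"""


class PanelCNVError(Exception):
    """Base class for all panelcnv errors."""


class InvalidParameterError(PanelCNVError, ValueError):
    """A numeric parameter violates its precondition (e.g. non-positive)."""


class InputError(PanelCNVError, ValueError):
    """Malformed or unusable input data (files, tables, intervals)."""


class ParseError(InputError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class EmptyOverlapError(InputError):
    """A coverage file shares no positions with the target panel."""


class NoEligibleNormalsError(InputError):
    """No normal sample survived the mean-depth cutoff."""


class InsufficientNormalsError(InputError):
    """Fewer eligible normal samples than the requested pool size."""


class TemplateMismatchError(InputError):
    """Two window-indexed objects were built from different templates."""


class UnknownGeneError(InputError):
    """A gene symbol is not present in the panel."""


class CrossLotError(InputError):
    """Query and pool set come from different capture-kit lots."""


class QCFailureError(PanelCNVError):
    """A hard quality-control failure (query/pool deviation above cutoff)."""
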