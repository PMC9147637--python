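"""Exception hierarchy for the EASA analysis pipeline.

Every contract violation raises a subclass of :class:`EasaError` so callers
(and the CLI) can distinguish validation problems from programming errors.
"""


class EasaError(Exception):
    """Base class for all assay-analysis errors."""


class CapacityError(EasaError):
    """More test chemicals requested than the plate design can hold."""


class FormatError(EasaError):
    """A file does not have the expected shape (rows/columns/header)."""


class ParseError(EasaError):
    """A cell could not be parsed as a number; message carries the well."""


class ValidationError(EasaError):
    """Parsed content violates a domain invariant."""


class SignalWindowError(EasaError):
    """No dynamic range: mean negative-control signal <= mean blank signal."""


class GroupEmptyError(EasaError):
    """QC exclusions reduced a well group to zero members."""


class InsufficientReplicatesError(EasaError):
    """A group has fewer than two wells, so its SD is undefined."""


class DegenerateVarianceError(EasaError):
    """All four group variances are zero; the T statistic is undefined."""


class QCIncompleteError(EasaError):
    """A required in-process control read or input is missing."""


class NotEvaluableError(EasaError):
    """No conclusive inputs are available for a call or a statistic."""


class ManifestError(EasaError):
    """A run manifest is missing a required plate read."""
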