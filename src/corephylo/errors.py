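"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`CorePhyloError` so the CLI can
report the failing stage and offending item without a traceback.
"""


class CorePhyloError(Exception):
    """Base class for all package errors."""


class ValidationError(CorePhyloError):
    """Invalid user input (counts, options, cross-option consistency)."""


class FormatError(CorePhyloError):
    """A file does not conform to its declared format."""


class SequenceTypeError(FormatError):
    """A proteome file looks like nucleotide data."""


class NewickParseError(FormatError):
    """Malformed Newick text; carries a character offset when known."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at character offset {offset})"
        super().__init__(message)
        self.offset = offset


class CalibrationError(CorePhyloError):
    """Profile-HMM E-value calibration failed (degenerate score distribution)."""


class SearchError(CorePhyloError):
    """Homolog search misuse (e.g. uncalibrated model)."""


class ConsistencyError(CorePhyloError):
    """Cross-referenced identifiers do not resolve (dangling seq_id etc.)."""


class CutoffError(ValidationError):
    """Prevalence cutoffs removed too much of the data set."""


class TrimError(CorePhyloError):
    """Alignment trimming produced an empty alignment or got bad input."""


class TreeError(CorePhyloError):
    """Tree construction / comparison misuse (leaf-set mismatch etc.)."""


class ExternalToolError(CorePhyloError):
    """An external command failed; carries its captured diagnostics."""

    def __init__(self, message: str, diagnostics: str = ""):
        super().__init__(message if not diagnostics else f"{message}\n--- captured output ---\n{diagnostics}")
        self.diagnostics = diagnostics


class PHDFormatError(FormatError):
    """Profile-HMM database file is truncated, corrupt, or wrong version."""
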