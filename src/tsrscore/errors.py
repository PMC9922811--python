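"""Exception hierarchy for TSR scoring.

Errors are grouped so that callers (and the CLI) can distinguish three
failure families: malformed inputs, biologically unassessable cases, and
numerical-integrity failures of the fast convolution path.
"""


class TSRError(Exception):
    """Base class for all package errors."""


class FormatError(TSRError):
    """A config, raster, ROI or score file is malformed."""


class ValidationError(TSRError):
    """Input data violates a declared contract (unknown class code, off-grid score...)."""


class EmptyROIError(ValidationError):
    """The circular ROI does not intersect the label map."""


class UnassessableROIError(TSRError):
    """ROI denominator is empty (all mucus/necrosis/background): TSR undefined."""


class EmptyBulkError(TSRError):
    """No tumor-gland pixels: no tumor bulk can be extracted."""


class CaseUnassessableError(TSRError):
    """Tumor bulk too narrow to fit the circular field of view, or all
    candidate centers fail the validity rules."""


class NumericalIntegrityError(TSRError):
    """FFT-derived pixel counts deviate from integers beyond tolerance."""


class UndefinedStatisticError(TSRError):
    """A requested statistic is undefined for the given data (e.g. zero
    variance, degenerate agreement table)."""


class InputError(TSRError):
    """Statistical input does not meet minimal size/shape requirements."""
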