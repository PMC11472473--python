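"""Exception hierarchy.

Errors distinguish bad parameters (caller mistakes), bad data (malformed or
insufficient input), and assay-invalid states (a plate that cannot be
analysed at all, e.g. no usable blank-control wells).
"""


class SfidaError(Exception):
    """Base class for all package errors."""


class ParameterError(SfidaError, ValueError):
    """Invalid configuration or function parameter."""


class DataError(SfidaError, ValueError):
    """Input data is malformed, empty, or insufficient for the operation."""


class AssayInvalidError(SfidaError, RuntimeError):
    """The assay run cannot be evaluated (e.g. no accepted blank images)."""


class CalibrationError(SfidaError, RuntimeError):
    """Calibration could not be established (no included points, singular fit,
    or non-positive slope)."""
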