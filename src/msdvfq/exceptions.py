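"""Exception hierarchy for msdvfq."""


class MsdvfqError(Exception):
    """Base class for all package errors."""


class DataValidationError(MsdvfqError, ValueError):
    """Raised when input data violate a structural requirement
    (non-integer cells, out-of-range categories, duplicate ids, ...)."""


class NoDataError(MsdvfqError, ValueError):
    """Raised when an estimate is requested for a respondent with no
    non-missing responses."""


class CalibrationError(MsdvfqError, RuntimeError):
    """Raised when a calibration is impossible, e.g. every item has an
    extreme score in every dichotomization."""


class ChecksumError(MsdvfqError, RuntimeError):
    """Raised when a packaged data file fails its integrity check."""
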