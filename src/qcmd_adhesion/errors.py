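"""Exception hierarchy for the QCM-D adhesion toolkit."""


class QcmError(Exception):
    """Base class for all package errors."""


class FormatError(QcmError):
    """A trace or table file does not conform to the expected layout."""


class DataError(QcmError):
    """Input data violate a structural requirement (e.g. non-monotone time)."""


class ConfigurationError(QcmError):
    """An archetype, preset or parameter set is internally inconsistent."""


class SingularLoadError(QcmError):
    """The lossless coupled resonator was evaluated exactly at its pole."""


class StabilizationError(QcmError):
    """No trailing window satisfied the stationarity (slope) tolerance.

    Carries the smallest slope magnitude that was achieved so callers can
    report how far the series was from stabilizing.
    """

    def __init__(self, message: str, best_slope: float):
        super().__init__(message)
        self.best_slope = best_slope


class SegmentationError(QcmError):
    """The trace is too short (or too degenerate) to segment."""


class AmbiguousSignPatternError(QcmError):
    """Determinate overtone signs are not single-crossing (e.g. +, -, +)."""


class InsufficientSignalError(QcmError):
    """Every overtone shift fell inside the dead-band; no sign can be called."""


class UndefinedRatioError(QcmError):
    """Dissipation/frequency ratio requested for a zero frequency shift."""


class LabelMismatchError(QcmError):
    """Surface labels of two tables being joined do not match."""

    def __init__(self, message: str, unmatched: list):
        super().__init__(message)
        self.unmatched = list(unmatched)
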