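"""Exception hierarchy shared across the pipeline."""


class FretscopeError(Exception):
    """Base class for all package errors."""


class ConfigError(FretscopeError):
    """Invalid configuration (scene, pipeline or CLI parameters)."""


class DataError(FretscopeError):
    """Input data violates a precondition (shape mismatch, empty mask...)."""


class CalibrationError(FretscopeError):
    """Bleed-through calibration cannot be performed on the given sample."""


class SegmentationError(DataError):
    """No usable cell footprint could be extracted from a frame."""


class FitError(FretscopeError):
    """Nonlinear fit failed to converge or returned inadmissible parameters."""
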