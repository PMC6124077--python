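"""Exception types raised across the pipeline."""


class FlukeprintError(Exception):
    """Base class for package errors."""


class ConfigurationError(FlukeprintError):
    """A simulation or pipeline configuration is internally inconsistent."""


class ReadError(FlukeprintError):
    """A single sequencing record is malformed (record-level, recoverable)."""


class CalibrationError(FlukeprintError):
    """Positive-control error calibration cannot be computed."""


class AlignmentError(FlukeprintError):
    """Sequences expected to be aligned/equal-length are not."""


class FitError(FlukeprintError):
    """A regression (e.g. qPCR standard curve) cannot be fitted."""
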