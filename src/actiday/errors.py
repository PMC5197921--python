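"""Exception hierarchy for the actiday pipeline."""


class ActidayError(Exception):
    """Base class for all actiday errors."""


class ConfigurationError(ActidayError):
    """Invalid configuration value or unknown configuration key."""


class InputError(ActidayError):
    """An input violates a precondition (too short, non-uniform, wrong rate...)."""


class CalibrationError(ActidayError):
    """Calibration could not be applied (unsuccessful model)."""


class MergeConflictError(ActidayError):
    """Device recordings overlap or belong to different participants."""


class MergeGapError(ActidayError):
    """Gap between device recordings too large to merge into one day."""


class DataError(ActidayError):
    """Data content is unusable (empty series, zero variance, collinearity...)."""
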