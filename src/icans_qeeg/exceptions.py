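"""Exception hierarchy shared across the pipeline."""


class QEEGError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(QEEGError):
    """Invalid configuration (bad filter setup, unknown covariate, bad bins...)."""


class FormatError(QEEGError):
    """Unreadable or malformed input file."""


class ChannelError(QEEGError):
    """Required EEG channels missing from a record."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"missing required channels: {', '.join(self.missing)}")


class AnnotationError(QEEGError):
    """Overlapping, negative-length or out-of-range artifact annotations."""


class SizeError(QEEGError):
    """Input too short / empty for the requested computation."""


class DataError(QEEGError):
    """Non-finite samples, negative rates, or otherwise invalid data values."""


class DegenerateError(QEEGError):
    """Computation undefined on this input (constant covariate, zero events...)."""


class NormalizationError(QEEGError):
    """Baseline feature unusable for ratio normalization."""

    def __init__(self, feature):
        self.feature = feature
        super().__init__(f"baseline feature {feature!r} is not strictly positive")


class FitError(QEEGError):
    """Model fit failed (separation / non-convergence); carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        self.diagnostics = diagnostics
        super().__init__(message)
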