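"""Exception and warning types shared across the pipeline."""


class PreAlphaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PreAlphaError):
    """File could not be parsed as EDF/EDF+."""


class MontageError(PreAlphaError):
    """A required 10-20 electrode is absent from the recording."""

    def __init__(self, missing):
        self.missing = tuple(missing) if not isinstance(missing, str) else (missing,)
        super().__init__(f"missing required electrode(s): {', '.join(self.missing)}")


class NyquistError(PreAlphaError):
    """Sampling rate too low for the requested band edge."""


class EpochLengthError(PreAlphaError):
    """Recording shorter than the analysis epoch; the method is undefined below 150 s."""


class ResolutionError(PreAlphaError):
    """Segment geometry incompatible with the native 0.5 Hz FFT bin spacing."""


class AggregationError(PreAlphaError):
    """Too few segments for a robust across-segment estimate."""


class RankingError(PreAlphaError):
    """Component ranking requires scores from both diagnostic classes."""


class ProjectionError(PreAlphaError):
    """Covariance tensor and PCA basis dimensions do not match."""


class CalibrationError(PreAlphaError):
    """Index scale undefined (zero spread in the AD training cohort)."""


class AgeRequiredError(PreAlphaError):
    """The index formula includes age terms; age must be supplied."""


class MetricsError(PreAlphaError):
    """Diagnostic metrics undefined for an empty class."""


class RunError(PreAlphaError):
    """A workflow command could not produce any output."""


class IdempotencyWarning(UserWarning):
    """Operation already applied; re-application is a no-op."""


class PooledFallbackWarning(UserWarning):
    """Gender stratum too small; falling back to the pooled model."""


class RowSkippedWarning(UserWarning):
    """A manifest row was skipped (missing field required by a rule)."""
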