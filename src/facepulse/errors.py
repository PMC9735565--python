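"""Exception hierarchy and process exit codes.

Every failure mode a pipeline run can hit maps to a distinct exception,
and each exception carries the exit code the CLI uses for it.
"""


class FacepulseError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(FacepulseError):
    """Invalid parameters, missing files, or an unusable detector setup."""

    exit_code = 2


class NoFaceDetectedError(FacepulseError):
    """No frame in the video produced a usable face detection."""

    exit_code = 3


class UnrecoverableGapError(FacepulseError):
    """A detection dropout gap exceeds the interpolation limit.

    Carries the offending gap's time span in seconds.
    """

    exit_code = 4

    def __init__(self, message: str, start_s: float | None = None, end_s: float | None = None):
        super().__init__(message)
        self.start_s = start_s
        self.end_s = end_s


class NoPulseDetectedError(FacepulseError):
    """Fewer than two pulse-wave (or ACF) peaks were found."""

    exit_code = 5


class DegenerateGeometryError(FacepulseError):
    """An ROI collapsed to zero area after rounding/clamping."""

    exit_code = 2


class EstimatorFailureError(FacepulseError):
    """An estimator failed internally (e.g. ICA unmixing did not converge)."""

    exit_code = 6


class UnusableFixtureError(ConfigurationError):
    """A synthetic scene's dropout pattern cannot be repaired downstream."""
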