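"""Exception hierarchy shared by all sipbiofilm modules."""


class SipBiofilmError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SipBiofilmError, ValueError):
    """A file or in-memory container violates the expected dialect."""


class ValidationError(SipBiofilmError, ValueError):
    """An in-memory object violates one of its invariants."""


class PlacementError(SipBiofilmError, ValueError):
    """A synthetic object cannot be placed on the requested canvas."""


class ThresholdError(SipBiofilmError, ValueError):
    """Automatic thresholding is degenerate (e.g. constant image)."""


class ConfigError(SipBiofilmError, ValueError):
    """A user-supplied recipe or configuration is malformed."""


class EmptyPopulationError(SipBiofilmError, ValueError):
    """A statistics operation received an empty population."""


class PairingError(SipBiofilmError, ValueError):
    """A paired test was requested for samples that cannot be paired."""


class DegenerateCovarianceError(SipBiofilmError, ValueError):
    """Covariance ellipse requested for (near-)collinear points."""


class RenderError(SipBiofilmError, ValueError):
    """An image cannot be rendered (e.g. no valid pixels)."""


class CalibrationError(SipBiofilmError, ValueError):
    """Too few clean standards remain to fit a two-point correction."""


class FitError(SipBiofilmError, ValueError):
    """A regression fit is inconsistent with its physical constraints."""


class PipelineStageError(SipBiofilmError, RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
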