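"""Exception types shared across the pipeline.

Every stage raises a subclass of :class:`OscippError` carrying a ``stage``
attribute so the orchestrator can label where a measurement failed.
"""


class OscippError(Exception):
    """Base class for all package errors."""

    stage: str = "generic"

    def __init__(self, message: str, **diagnostics):
        super().__init__(message)
        self.diagnostics = diagnostics


class SchemaError(OscippError):
    """A file or table does not match the expected schema/invariants."""

    stage = "io"


class BeatDetectionError(OscippError):
    stage = "detect_beats"


class OscillogramError(OscippError):
    """Too few beats, or the discrete oscillogram is unusable."""

    stage = "build_oscillogram"


class FitError(OscippError):
    """Nonlinear least squares failed or the data admit no inverted-U fit."""

    stage = "fit_oscillogram"


class DerivativeError(OscippError):
    """The fitted curve's derivative lacks a sign-changing extrema pair."""

    stage = "compute_pp"


class ValidityError(OscippError):
    stage = "validity"


class ScreeningError(OscippError):
    stage = "screening"
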