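"""Exception hierarchy for myotrace.

Every stage of the pipeline raises a subclass of :class:`MyotraceError`, so
callers can catch one base class and still discriminate failure modes
(format problems, missing annotations, quantification preconditions).
"""


class MyotraceError(Exception):
    """Base class for all myotrace errors."""


class TraceFormatError(MyotraceError):
    """Malformed trace file: non-monotonic time, NaN tension, bad columns."""


class AnnotationError(MyotraceError):
    """Missing or malformed event-annotation sidecar."""


class DomainError(MyotraceError):
    """Argument outside the operation's domain (bad group label, fold < 1, ...)."""


class NonStationaryError(MyotraceError):
    """No segment with stable basal tension long enough for quantification."""


class DegenerateHistogramError(MyotraceError):
    """Amplitude histogram cannot be built (constant segment, too few samples)."""


class FitConvergenceError(MyotraceError):
    """Two-Gaussian histogram fit failed to converge after restarts."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NoDominantRhythmError(MyotraceError):
    """Power spectrum has no peak exceeding the prominence threshold."""


class ResolutionError(MyotraceError):
    """Segment too short for the requested spectral resolution or envelope."""


class NormalizationError(MyotraceError):
    """KCl reference contraction missing, so amplitudes cannot be normalized."""


class QualityError(MyotraceError):
    """Recording fails a quality gate (e.g. non-positive KCl amplitude)."""


class AmbiguousWindowError(MyotraceError):
    """Overlapping response windows make single-train attribution impossible."""


class StageError(MyotraceError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage, cause):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause
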