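"""Named failure modes.

Every rejected input raises a distinct subclass of :class:`SpermfxError`
so callers can distinguish malformed files from unanalyzable-but-valid
data (short segments, degenerate calibrations, ...).
"""


class SpermfxError(Exception):
    """Base class for all spermfx failures."""


class TraceFormatError(SpermfxError):
    """A trace or track file does not conform to the expected layout."""


class NonMonotonicTimeError(TraceFormatError):
    """Trace time stamps are not strictly increasing and uniformly spaced."""


class EventRangeError(TraceFormatError):
    """An annotated event lies outside the sampled time range."""


class MissingEventError(SpermfxError):
    """A required reagent-addition event is absent from the trace."""


class EventOrderError(SpermfxError):
    """Reagent-addition events are present but in a physiologically wrong order."""


class SegmentTooShortError(SpermfxError):
    """A trace segment has too few samples for the requested statistic."""


class CalibrationInvalidError(SpermfxError):
    """The fluorescence-vs-potential calibration is degenerate (flat or nonlinear)."""


class NormalizationDegenerateError(SpermfxError):
    """Basal fluorescence is non-positive after quench normalization."""


class TrackError(SpermfxError):
    """Base class for trajectory problems."""


class DuplicateFrameError(TrackError):
    """The same (track id, frame) pair occurs more than once."""


class TrackTooShortError(TrackError):
    """A track has fewer frames than the kinematic smoothing window."""


class SpecValidationError(SpermfxError):
    """A synthetic-data specification violates its invariants."""
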