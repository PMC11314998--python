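"""Exception hierarchy for the autofocus pipeline.

Every failure mode that a caller may want to handle programmatically gets
its own class; plain ``ValueError`` is reserved for malformed arguments.
"""


class FocusError(Exception):
    """Base class for all fieldfocus-specific errors."""


class FieldOutOfBoundsError(FocusError):
    """The illumination field (plateau + blur margin) would leave the detector."""


class NoFieldDetectedError(FocusError):
    """The gradient profile has no usable rising/falling edge pair."""


class InvertedEdgesError(FocusError):
    """The falling edge precedes the rising edge (pathological input)."""


class DegenerateCurveError(FocusError):
    """The fitted evaluation curve has |k| below the usability floor."""


class TravelExceededError(FocusError):
    """A commanded stage move exceeds the actuator travel range."""


class ImageFormatError(FocusError):
    """An input image file is not 2-D grayscale 8/16-bit."""
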