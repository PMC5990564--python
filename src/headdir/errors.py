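"""Exceptions raised by the head-direction coding pipeline."""


class HeadDirError(Exception):
    """Base class for all package errors."""


class DimensionMismatchError(HeadDirError):
    """Frame and background (or two compared frames) differ in shape."""


class InsufficientForegroundError(HeadDirError):
    """Binary mask holds fewer foreground points than the requested k."""


class EarsNotFoundError(HeadDirError):
    """Fewer than two contours survived filtering in the ear-tuft algorithm."""


class TagNotFoundError(HeadDirError):
    """No pixel fell inside the colour-tag HSV range (zeroth moment is zero)."""


class DegenerateGeometryError(HeadDirError):
    """hPos and bPos coincide; the head direction is undefined."""


class SessionLayoutError(HeadDirError):
    """Frame folder violates the naming convention (missing bg, index gap...)."""


class LedOnsetNotFoundError(HeadDirError):
    """No frame's white mass departed from the baseline by more than the threshold."""


class LogFormatError(HeadDirError):
    """Session log violates the format or its ordering invariants."""


class TrialWindowError(HeadDirError):
    """A trial's extraction window falls outside the recorded frame sequence."""
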