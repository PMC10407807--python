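"""Exception hierarchy shared across the package."""


class CarotextureError(ValueError):
    """Base class for all domain errors raised by this package."""


class EmptyMaskError(CarotextureError):
    """An operation requiring a non-empty pixel mask received an empty one."""


class NoPairsError(CarotextureError):
    """No valid pixel pair fell inside the mask for any displacement."""


class DegenerateReferenceError(CarotextureError):
    """Adventitia reference is not strictly brighter than the blood reference."""


class TraceError(CarotextureError):
    """Wall traces are too short, crossing, or enclose an empty band."""


class SizingError(CarotextureError):
    """Requested phantom geometry does not fit inside the wall band."""


class AnnotationError(CarotextureError):
    """An elastin line annotation violates its validity constraints."""
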