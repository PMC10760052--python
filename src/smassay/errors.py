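"""Exception hierarchy for smassay."""


class SmassayError(Exception):
    """Base class for all smassay errors."""


class ParameterError(SmassayError, ValueError):
    """A simulation or analysis parameter violates its invariants."""


class PlacementError(SmassayError, RuntimeError):
    """Spot placement with the requested minimum separation did not terminate."""


class FieldMismatchError(SmassayError, ValueError):
    """Two spot sets that must come from the same field of view do not."""


class InputError(SmassayError, ValueError):
    """Malformed or insufficient input data."""


class EdgeError(SmassayError, ValueError):
    """A photometry aperture or annulus extends beyond the image."""


class SaturationError(SmassayError, ValueError):
    """A fully-on bead array cannot be inverted to enzymes per bead."""


class CurveError(SmassayError, ValueError):
    """A standard curve is unusable (non-positive slope, missing blanks)."""
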