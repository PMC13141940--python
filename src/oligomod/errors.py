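"""Exception types shared across the package."""


class OligomodError(Exception):
    """Base class for all package errors."""


class FormatError(OligomodError):
    """A file could not be parsed in the declared format."""


class EmptyStructureError(OligomodError):
    """A coordinate file contained no polymer protein atoms."""


class PairingError(OligomodError):
    """Coordinate sets could not be paired for superposition."""


class ConditioningError(OligomodError):
    """Degenerate geometry (collinear or near-collinear point set)."""


class SpecError(OligomodError):
    """An operation specification violated its invariants."""


class RadiusLookupError(OligomodError):
    """No van der Waals radius is tabulated for an atom."""
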