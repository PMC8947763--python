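"""Exception hierarchy used across the package."""


class TetraporeError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(TetraporeError):
    """A coordinate file could not be parsed."""


class EmptyModelError(TetraporeError):
    """A structure contained no atoms where at least one was required."""


class FieldOverflowError(TetraporeError):
    """A value does not fit the fixed-width fields of the output format."""


class EmptySelectionError(TetraporeError):
    """An atom selection matched nothing."""


class SymmetryError(TetraporeError):
    """Protomer assignment failed (wrong chain count, no C4 partition)."""


class DegenerateGeometryError(TetraporeError):
    """Input geometry is degenerate (collinear/coplanar) for the operation."""


class PoreEnclosureError(TetraporeError):
    """The pore selection does not enclose the channel axis."""
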