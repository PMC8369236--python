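"""Package-specific exceptions."""


class BraggShiftError(Exception):
    """Base class for package errors."""


class UnsupportedGeometryError(BraggShiftError):
    """Beam/field geometry outside the supported perpendicular setup."""


class IncompatibleGridsError(BraggShiftError):
    """Two dose grids cannot be compared (mismatched geometry or beam)."""


class NoPeakError(BraggShiftError):
    """A dose grid contains no usable maximum."""


class FitError(BraggShiftError):
    """A least-squares fit failed to converge."""


class ContourError(BraggShiftError):
    """An isodose contour is open, degenerate or missing."""


class FormatError(BraggShiftError):
    """A dose-grid file misses required header or provenance entries."""


class FixtureError(BraggShiftError):
    """A packaged reference table is unknown or fails its checksum."""
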