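"""Exception hierarchy shared across the package."""


class ChloromotionError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ChloromotionError):
    """A file or header does not conform to the expected format."""


class TruncationError(FormatError):
    """Binary payload smaller than the header declares."""


class CalibrationError(ChloromotionError):
    """White/dark reference does not permit reflectance calibration."""


class BandRangeError(ChloromotionError):
    """Requested wavelength lies outside the grid (plus tolerance)."""


class SegmentationError(ChloromotionError):
    """Leaf segmentation produced an empty or invalid mask."""


class GeometryError(ChloromotionError):
    """A dividing line or region is geometrically invalid."""


class DegenerateLabelError(ChloromotionError):
    """A binary-label computation received a single-group input."""


class ProtocolError(ChloromotionError):
    """An evaluation protocol constraint was violated (e.g. species overlap)."""


class UndefinedValueError(ChloromotionError):
    """An index evaluated to 0/0 or an otherwise undefined value."""
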