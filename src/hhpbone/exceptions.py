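"""Exception types shared across the package.

All are ``ValueError`` subclasses so callers can catch broadly, but each
pipeline stage raises a named type so errors propagate with their stage
visible.
"""


class HhpboneError(ValueError):
    """Base class for all package-specific errors."""


class ConfigError(HhpboneError):
    """Invalid or empty configuration (e.g. an empty fragment spec)."""


class PlacementError(HhpboneError):
    """Requested cell count cannot be packed into the available area."""


class LayoutError(HhpboneError):
    """Tile count does not match the requested tile layout."""


class DegenerateImageError(HhpboneError):
    """Image has too few distinct gray levels to threshold."""


class AlignmentError(HhpboneError):
    """Mask and density-grid geometries are incompatible."""


class ZoneError(HhpboneError):
    """A radial zone contains no masked-in bins."""


class CalibrationError(HhpboneError):
    """Too few ladder rungs, or calibration otherwise impossible."""


class PairingError(HhpboneError):
    """Band-to-rung pairing is non-monotone or inconsistent."""


class IdentificationError(HhpboneError):
    """Expected band pattern (e.g. the alpha-chain pair) not found."""


class AmbiguityError(IdentificationError):
    """More than one candidate band pattern; refusing to choose silently."""


class DesignError(HhpboneError):
    """Factorial design invalid (too few levels, unbalanced, no residual df)."""


class ChannelMismatchError(HhpboneError):
    """Image does not have the expected number of channels."""
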