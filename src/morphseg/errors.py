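"""Exception hierarchy.

All package-specific failures derive from :class:`MorphSegError` so callers
can catch one base class; most also derive from ``ValueError`` because they
signal invalid inputs rather than internal faults.
"""


class MorphSegError(Exception):
    """Base class for all morphseg errors."""


class ChannelTagError(MorphSegError, ValueError):
    """A color image carried the wrong channel-space tag for an operation."""


class InvalidElementError(MorphSegError, ValueError):
    """A structuring element is empty or its origin lies outside the support."""


class OrderingError(MorphSegError, ValueError):
    """Marker/mask ordering required by a geodesic operator is violated."""


class ShapeMismatchError(MorphSegError, ValueError):
    """Two rasters that must share a shape do not."""


class ConfigError(MorphSegError, ValueError):
    """An invalid parameter value (negative depth, non-ascending scales...)."""


class DegenerateHistogramError(MorphSegError, ValueError):
    """Otsu thresholding was asked to split a single-valued histogram."""


class NoMarkerError(MorphSegError, ValueError):
    """Marker extraction produced an empty marker set."""


class EmptySampleError(MorphSegError, ValueError):
    """A statistical test received an empty (or too small) sample."""


class PackingError(MorphSegError, RuntimeError):
    """The synthetic-scene generator could not place all objects."""
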