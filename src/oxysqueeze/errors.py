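"""Exception types raised across the pipeline."""


class OxysqueezeError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(OxysqueezeError, ValueError):
    """A configuration value violates its documented constraints."""


class MissingInputError(OxysqueezeError, KeyError):
    """A required input (e.g. a water level for a requested date) is absent."""


class UnsupportedRasterError(OxysqueezeError, ValueError):
    """The raster cannot be used (non-square cells, wrong band count...)."""


class EmptyRasterError(OxysqueezeError, ValueError):
    """The raster contains no valid (non-nodata) cells."""


class AlignmentError(OxysqueezeError, ValueError):
    """Two grids do not share shape and geotransform."""


class IncompleteProfileError(OxysqueezeError, ValueError):
    """A daily profile is missing one or more required depth rows."""


class NoOverlapError(OxysqueezeError, ValueError):
    """Two inputs share no dates/years, so nothing can be computed."""


class InsufficientDataError(OxysqueezeError, ValueError):
    """Too few usable rows to fit the requested model."""
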