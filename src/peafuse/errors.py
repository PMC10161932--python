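"""Exception hierarchy.

Every error raised on a contract violation derives from :class:`PeafuseError`
so callers can catch pipeline failures without swallowing programming errors.
"""


class PeafuseError(Exception):
    """Base class for all peafuse errors."""


class InvalidDesignError(PeafuseError):
    """Trial design with non-positive counts or impossible layout."""


class GeometryError(PeafuseError):
    """Plot geometry outside the scene, empty ROI, or invalid polygon."""


class ResolutionError(PeafuseError):
    """Non-integer GSD ratio or incompatible grid shapes."""


class AlignmentError(PeafuseError):
    """Scenes whose world frames disagree beyond tolerance."""


class BandError(PeafuseError):
    """A required spectral band cannot be resolved on a scene."""


class FormatError(PeafuseError):
    """File content violates the declared raster/vector contract."""


class MetadataError(PeafuseError):
    """Missing or unparseable georeferencing metadata."""


class ContractError(PeafuseError):
    """Operation precondition violated (shapes, band counts, ...)."""


class ParameterError(PeafuseError):
    """Out-of-range algorithm parameter (wavelet levels, percentile, ...)."""


class SplitError(PeafuseError):
    """Train/test split impossible (single entry, empty side, ...)."""


class DataError(PeafuseError):
    """Feature table unusable for modeling (all-missing column, ...)."""


class PipelineError(PeafuseError):
    """A whole pipeline stage produced no usable output."""
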