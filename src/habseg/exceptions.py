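"""Exception and warning types used across the package."""


class HabsegError(Exception):
    """Base class for all package-specific errors."""


class DimensionalityError(HabsegError):
    """Image is not a 3D scalar volume."""


class BoundsError(HabsegError, IndexError):
    """Voxel index outside the image grid."""


class DegenerateGeometryError(HabsegError, ValueError):
    """Landmarks do not define the required geometry (coincident/collinear)."""


class NoIntersectionError(DegenerateGeometryError):
    """The two boundary lines do not intersect (parallel configuration)."""


class DegeneratePolygonError(DegenerateGeometryError):
    """Constructed polygon has zero area or an invalid apex."""


class LeakageError(HabsegError, RuntimeError):
    """Intensity region growing escaped its clip box: contrast insufficient."""


class ContiguityError(HabsegError, ValueError):
    """Slice masks do not form a contiguous coronal stack."""


class UndefinedICCError(HabsegError, ValueError):
    """ICC undefined (e.g. zero total variance)."""


class IncompleteDesignError(HabsegError, ValueError):
    """Rater table has missing cells or too few subjects/raters."""


class AlignmentError(HabsegError, ValueError):
    """Subject lists of the two raters do not match."""


class ConfigurationError(HabsegError, ValueError):
    """Phantom specification cannot be realised on the requested grid."""


class ProtocolWarning(UserWarning):
    """Input is usable but outside the protocol's expected envelope."""
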