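"""Exception hierarchy for navigation-chain failures."""


class NavigationError(Exception):
    """Base class for all arnav errors."""


class FrameMismatchError(NavigationError):
    """Two transforms or point sets live in incompatible coordinate frames."""


class DegenerateGeometryError(NavigationError):
    """Point configuration or linear system too degenerate to solve."""


class LabelMismatchError(NavigationError):
    """Paired fiducial sets whose labels do not correspond."""


class GridMismatchError(NavigationError):
    """Two volumes that must share a voxel grid do not."""


class OutOfBoundsError(NavigationError):
    """A point falls outside the volume or image bounds."""


class NoIntersectionError(NavigationError):
    """A cast ray does not hit the requested surface."""


class BehindProjectorError(NavigationError):
    """A point has non-positive depth in the projector frame."""


class UnsupportedImageError(NavigationError):
    """Image file with geometry or dtype outside the supported subset."""
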