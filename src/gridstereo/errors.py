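"""Exception hierarchy.

Every failure mode the pipeline can signal maps onto one of these classes so
that callers (and the CLI exit-code table) can dispatch on failure family.
"""


class GridStereoError(Exception):
    """Base class for all errors raised by gridstereo."""


class ConfigError(GridStereoError):
    """Invalid or unknown configuration / calibration content."""


class NonProjectablePointError(GridStereoError):
    """A 3D point lies at or behind the camera center."""


class DistortionInversionError(GridStereoError):
    """Iterative undistortion failed to converge."""


class DegenerateRigError(GridStereoError):
    """Stereo rig with zero baseline or otherwise unusable geometry."""


class NonTriangulablePairError(GridStereoError):
    """Back-projected rays are parallel; no unique midpoint exists."""


class DegenerateGeometryError(GridStereoError):
    """Too few or degenerate (e.g. collinear) points for a rigid fit."""


class NoPatternFoundError(GridStereoError):
    """No gridline pattern region could be located in the image."""


class DegenerateLayoutError(GridStereoError):
    """Detected points cannot be organised into a grid layout."""


class PatternNotVisibleError(GridStereoError):
    """The projected pattern falls (partly) outside the rendered views."""
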