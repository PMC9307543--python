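"""Exception hierarchy for cranionav.

All domain errors derive from :class:`CranionavError` so callers can catch
one base class; the concrete subclasses distinguish the failure modes the
pipeline has to handle explicitly (degenerate geometry, disconnected frame
graphs, contradictory calibrations, curve pairs with no usable overlap).
"""


class CranionavError(Exception):
    """Base class for all cranionav domain errors."""


class InvalidTransformError(CranionavError):
    """Rotation matrix is not orthonormal with determinant +1."""


class InvalidParameterError(CranionavError):
    """A scalar parameter is out of its valid range (e.g. step <= 0)."""


class DegenerateInputError(CranionavError):
    """Input geometry is unusable: too few points, collinear landmark
    configuration, label mismatch, empty mesh, zero-length curve."""


class UnreachableFrameError(CranionavError):
    """No path connects the requested coordinate frames."""


class FrameConsistencyError(CranionavError):
    """Two paths through the frame graph yield transforms that disagree
    beyond tolerance — a contradictory calibration."""


class NoOverlapError(CranionavError):
    """Reference and drawn curves share no usable arc-length overlap."""
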