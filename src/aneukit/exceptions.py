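"""Exception hierarchy.

All package-specific failures derive from :class:`AneukitError` so callers
can catch one base class at pipeline level.
"""


class AneukitError(Exception):
    """Base class for all aneukit errors."""


class MeshFormatError(AneukitError):
    """File could not be parsed in the requested/declared mesh format."""


class UnsupportedGeometryError(AneukitError):
    """Mesh contains cells other than triangles."""


class DegenerateGeometryError(AneukitError):
    """A triangle has (numerically) zero area."""


class DimensionError(AneukitError):
    """An attached data array does not match the mesh size."""


class TopologyError(AneukitError):
    """Surface topology inconsistent with the requested operation."""


class OrientationError(AneukitError):
    """Surface/neck-plane orientation is inconsistent (e.g. dome below plane)."""


class GenerationError(AneukitError):
    """Synthetic-data generation failed (unmeshable spec, bad correlation)."""


class PlacementError(AneukitError):
    """A planted flow feature lies outside the dome region."""


class StabilityError(AneukitError):
    """Explicit time integration diverged (time step too large)."""


class SeparationError(AneukitError):
    """Logistic regression detected (quasi-)complete separation."""
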