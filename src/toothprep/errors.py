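"""Exception hierarchy for the evaluation pipeline.

Every stage raises a subclass of :class:`ToothPrepError` carrying the stage
name, so a failed end-to-end run can report *where* it stopped.
"""


class ToothPrepError(Exception):
    """Base class for all pipeline errors."""

    stage = "toothprep"


class MeshFormatError(ToothPrepError):
    """File could not be parsed as STL or PLY."""

    stage = "mesh_io"


class DegenerateInputError(ToothPrepError):
    """Mesh empty (or empty after cleaning), or geometrically unusable."""

    stage = "mesh_io"


class RegistrationWarning(UserWarning):
    """ICP did not converge to a tight residual (e.g. non-overlapping inputs)."""


class SeedingError(ToothPrepError):
    """Root-area seed ring could not be placed on the anatomical mesh."""

    stage = "margin.seed"


class NoMarginFoundError(ToothPrepError):
    """Crown-ward walk reached the top of the mesh without diverging from the
    prepared surface; the two meshes are identical within the error bound."""

    stage = "margin.trace"


class ConnectivityError(ToothPrepError):
    """No edge path exists between two margin anchors."""

    stage = "margin.connect"


class ProjectionError(ToothPrepError):
    """Projected boundary polygon is self-intersecting."""

    stage = "margin.width"


class RegionError(ToothPrepError):
    """Axial/occlusal region boundary could not be constructed."""

    stage = "regions"


class GeometryError(ToothPrepError):
    """Invalid geometric input (zero-length normal, empty face set...)."""

    stage = "metrics"


class TaperUndefinedError(GeometryError):
    """Average taper requested for an empty face set / quadrant."""


class RubricError(ToothPrepError):
    """Unknown grading criterion or malformed rubric."""

    stage = "grading"


class IncompleteMeasurementError(ToothPrepError):
    """A graded field is missing from a measurement set."""

    stage = "grading"


class AgreementInputError(ToothPrepError):
    """Malformed ratings input (length mismatch, missing cells...)."""

    stage = "agreement"


class GenerationError(ToothPrepError):
    """Phantom specification violates its invariants."""

    stage = "synthetic"
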