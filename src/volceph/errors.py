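"""Exception hierarchy shared by all volceph modules."""


class VolcephError(Exception):
    """Base class for all package errors."""


class DegeneratePlaneError(VolcephError):
    """Points that should define a plane are (nearly) collinear or coincident."""


class MeshIntegrityError(VolcephError):
    """Mesh violates a watertightness / orientation invariant.

    Parameters
    ----------
    message : str
    boundary_edges : int, optional
        Number of open (boundary) edges found, when relevant.
    """

    def __init__(self, message: str, boundary_edges: int | None = None):
        if boundary_edges is not None:
            message = f"{message} ({boundary_edges} boundary edges)"
        super().__init__(message)
        self.boundary_edges = boundary_edges


class OrientationError(MeshIntegrityError):
    """Signed volume is negative or winding is inconsistent."""

    def __init__(self, message: str):
        super().__init__(message)


class TriangulationError(VolcephError):
    """Cap cross-section could not be triangulated."""


class VoxelBudgetError(VolcephError):
    """Requested voxel size would exceed the configured cell budget."""


class LandmarkError(VolcephError):
    """Landmark set is incomplete, duplicated, non-finite or degenerate."""


class PlaneStackError(VolcephError):
    """Anatomical plane stack failed validation and segmentation was refused."""


class CalibrationError(VolcephError):
    """Closed-loop share calibration did not converge."""


class CohortError(VolcephError):
    """Cohort table / jury score table violates its contract."""
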