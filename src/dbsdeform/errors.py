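"""Exception hierarchy.

Every error raised on a contract violation derives from :class:`DbsDeformError`
so pipeline code can wrap any stage failure with its stage name and case id.
"""


class DbsDeformError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(DbsDeformError, ValueError):
    """A caller-supplied argument violates a precondition."""


class EmptySegmentationError(DbsDeformError):
    """Thresholding selected no voxels (threshold likely too high)."""


class ComponentNotFoundError(DbsDeformError):
    """Fewer qualifying elongated components than electrodes requested.

    Carries per-component diagnostics in ``diagnostics`` (label, size, ratio).
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class DegenerateElectrodeError(DbsDeformError):
    """Component too short/compact to carry a centerline."""


class AmbiguousOriginError(DbsDeformError):
    """The stated proximal point is near neither end of the skeleton."""


class FitFailureError(DbsDeformError):
    """Polynomial regression failed (rank-deficient design)."""


class DegenerateCurveError(DbsDeformError):
    """Curve chord has zero length; deviations are undefined."""


class IrregularCurveError(DbsDeformError):
    """Curve speed vanishes at a sample; Frenet frame undefined there."""


class InvalidFrontiersError(InvalidArgumentError):
    """Tissue frontier distances violate their required ordering."""


class MissingLayerError(DbsDeformError):
    """A brain tissue layer contains no profile samples."""


class UndefinedICCError(DbsDeformError):
    """Both variance components are zero; ICC is 0/0."""


class ModelFailureError(DbsDeformError):
    """Mixed-model fit failed (singular design, non-convergence)."""


class InsufficientDataError(DbsDeformError):
    """Too few observations for the requested statistical test."""


class FormatError(DbsDeformError):
    """Malformed input file (bad NIfTI header, non-invertible affine...)."""


class PipelineStageError(DbsDeformError):
    """Wraps any stage failure with stage name and case id."""

    def __init__(self, stage, case_id, cause):
        super().__init__(f"stage '{stage}' failed for case '{case_id}': {cause}")
        self.stage = stage
        self.case_id = case_id
        self.cause = cause
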