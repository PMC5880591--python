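"""Exception hierarchy.

``ValidationFailure`` subclasses signal bad or inconsistent *input* (CLI exit
code 2); everything else derived from :class:`EpidoseError` is a runtime
failure (exit code 1).
"""


class EpidoseError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationFailure(EpidoseError):
    """Invalid input data, geometry, or fixture content."""

    exit_code = 2


class InvalidGeometryError(ValidationFailure):
    """Non-physical geometry (non-positive distances, field sizes, ...)."""


class OutOfRangeError(ValidationFailure):
    """Table query outside the axis range plus the extrapolation margin."""


class UnsupportedRegionError(ValidationFailure):
    """Point in the build-up region (depth < D_max), where TMR is undefined."""


class DegenerateInputError(ValidationFailure):
    """Zero or negative quantity where a positive one is required."""


class UndefinedReferenceError(DegenerateInputError):
    """Reference (TPS) dose is zero; a local deviation cannot be scored."""


class PairingError(ValidationFailure):
    """A with-absorber record has no matching open-field reference."""


class TableValidationError(ValidationFailure):
    """A dosimetric table violates its invariants (bounds, monotonicity)."""


class IncompleteGridError(ValidationFailure):
    """Commissioning grid cells without measurements or TPS points."""


class ConvergenceError(EpidoseError):
    """Iterative TPS correction did not converge within the iteration cap."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class OffImagerError(EpidoseError):
    """A point's ray projection misses the imager panel."""


class PlanIntegrityError(ValidationFailure):
    """Plan and delivery fixtures disagree (e.g. a beam without an image)."""


class FixtureFormatError(ValidationFailure):
    """Unreadable fixture file or unknown/unsupported schema version."""


class DicomTagError(FixtureFormatError):
    """A required DICOM tag is absent."""


class TemplateError(ValidationFailure):
    """Unknown synthetic plan template."""


class SamplingError(EpidoseError):
    """Too few qualifying voxels for the requested number of auto-POIs."""
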