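"""Exception hierarchy shared across the pipeline stages."""


class ToadhopError(Exception):
    """Base class for all package errors."""


class ParameterError(ToadhopError, ValueError):
    """A physical or configuration parameter is outside its valid range."""


class SynchronizationError(ToadhopError):
    """No usable flash spike found in a brightness trace."""


class DegenerateGeometryError(ToadhopError):
    """Camera resection attempted on too few or coplanar-only points."""


class TriangulationError(ToadhopError):
    """Viewing rays too close to parallel (or cameras coincident)."""


class TrajectoryGapError(ToadhopError):
    """Landmark stream has a gap too long to interpolate."""

    def __init__(self, message, gaps=None):
        super().__init__(message)
        self.gaps = gaps or []


class NoJumpDetectedError(ToadhopError):
    """Cloaca never rises above baseline + epsilon (or never lands)."""


class HeadingUndefinedError(ToadhopError):
    """Zero net horizontal displacement: travel direction undefined."""


class InsufficientFramesError(ToadhopError):
    """Take-off/landing bracket too short for kinematic extraction."""


class NoDataError(ToadhopError):
    """An operation received an empty collection."""


class DegenerateFitError(ToadhopError):
    """Regression group too small or SVL variance zero."""


class NestingDegeneracyError(ToadhopError):
    """A category contains a single population: nested term untestable."""


class RankDeficiencyError(ToadhopError):
    """More trait contrasts than residual degrees of freedom."""


class CollinearityError(ToadhopError):
    """Predictors collinear beyond conditioning tolerance."""

    def __init__(self, message, pair=None):
        super().__init__(message)
        self.pair = pair


class UndefinedCorrelationError(ToadhopError):
    """Correlation undefined (zero variance or n < 3)."""


class DataIntegrityError(ToadhopError):
    """Input table violates an internal consistency requirement."""


class InsufficientOverlapError(ToadhopError):
    """Fewer than 3 animals shared between joined datasets."""


class SchemaError(ToadhopError, ValueError):
    """CSV table does not match its documented schema."""
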