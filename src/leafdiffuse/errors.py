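"""Exception hierarchy shared by all pipeline stages."""


class LeafDiffuseError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(LeafDiffuseError):
    """A table is malformed: missing column, bad unit annotation, unparseable cell."""


class DataValidationError(LeafDiffuseError):
    """A record or measurement violates a physical invariant."""


class DomainError(LeafDiffuseError):
    """An argument is outside the mathematical domain of an operation."""


class InsufficientDataError(LeafDiffuseError):
    """Too few points (or a degenerate design) for the requested estimate."""


class CalibrationError(LeafDiffuseError):
    """The alpha*beta light calibration produced a non-usable slope."""


class DegeneracyError(LeafDiffuseError):
    """A denominator collapsed (variable-J with J <= 4(A+Rd), Ci == Cc, ...)."""


class FitError(LeafDiffuseError):
    """A nonlinear fit failed to converge or produced unusable parameters."""


class NoIntersectionError(LeafDiffuseError):
    """Laisk lines are near-parallel; no common intersection can be estimated."""


class SimulationError(LeafDiffuseError):
    """The synthetic-leaf forward problem has no physical solution."""


class PipelineError(LeafDiffuseError):
    """A pipeline stage failed; message names the stage and genotype."""
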