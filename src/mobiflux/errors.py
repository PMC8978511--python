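"""Exception hierarchy.

Every validation failure raises a distinct, named error so callers (and the
CLI) can report which contract was broken without parsing messages.
"""


class MobifluxError(Exception):
    """Base class for all package errors."""


class ValidationError(MobifluxError):
    """A domain invariant was violated by input data."""


class DuplicateIdError(ValidationError):
    """Two locations share the same identifier."""


class InvalidPopulationError(ValidationError):
    """A location population is not a positive integer."""


class CoordinateRangeError(ValidationError):
    """Latitude outside [-90, 90] or longitude outside [-180, 180]."""


class UnknownLocationError(ValidationError):
    """A record references a location id absent from the location table."""


class SelfLoopError(ValidationError):
    """A flow record has origin == destination."""


class NegativeFlowError(ValidationError):
    """A flow count is negative or non-integer."""


class DuplicateRecordError(ValidationError):
    """More than one record for the same (date, origin, destination) or (date, location)."""


class StarConstraintError(ValidationError):
    """A flow record does not touch the hub of an egocentric star panel."""


class StringencyRangeError(ValidationError):
    """A stringency index value lies outside [0, 100]."""


class MissingCovariateError(ValidationError):
    """A (date, location) pair required by a regression design has no stringency value."""


class AlignmentError(ValidationError):
    """Two time series do not share the same date index."""


class DegenerateDataError(MobifluxError):
    """Input admits no meaningful fit (e.g. all observed flows are zero)."""


class SingularDesignError(MobifluxError):
    """The regression design matrix is rank deficient."""


class FitConvergenceError(MobifluxError):
    """An optimizer failed to converge; carries the optimizer status."""

    def __init__(self, message: str, status=None):
        super().__init__(message)
        self.status = status


class OverflowRiskError(MobifluxError):
    """Generator parameters would overflow exp() before sampling."""


class ConfigurationError(MobifluxError):
    """An invalid option combination or malformed run configuration."""


class FlatResidualWarning(UserWarning):
    """The fit objective is (nearly) flat in a parameter; estimate is not identified."""
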