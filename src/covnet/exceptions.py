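"""Exception hierarchy for covnet.

Everything derives from :class:`CovnetError` so callers can catch the
package's own failures without masking programming errors.
"""


class CovnetError(Exception):
    """Base class for all covnet errors."""


class AtlasNotFoundError(CovnetError, KeyError):
    """Requested atlas identifier is not packaged and is not a readable file."""


class ValidationError(CovnetError, ValueError):
    """An input object violates a documented invariant."""


class TableParseError(ValidationError):
    """A stats or covariate table could not be parsed; names the offending cell."""


class ConsistencyError(ValidationError):
    """Subject ids or ROI labels disagree between inputs."""


class DegenerateDesignError(ValidationError):
    """Regression design matrix is rank deficient or has too few subjects."""


class UndefinedCorrelationError(ValidationError):
    """A zero-variance ROI column makes the Pearson correlation undefined."""


class ParameterError(CovnetError, ValueError):
    """A numeric parameter is outside its documented range."""


class DesignError(ValidationError):
    """A comparison design is invalid (overlapping groups, broken pairs...)."""


class UndefinedAUCError(CovnetError, ValueError):
    """A metric curve is NaN at every grid point; no AUC exists."""
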