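"""Exception hierarchy for the kincomm pipeline.

Every stage raises a subclass of :class:`KincommError` so callers can catch
pipeline failures without masking programming errors.
"""


class KincommError(Exception):
    """Base class for all kincomm errors."""


class FormatError(KincommError):
    """A file could not be parsed (names the offending row where possible)."""


class ValidationError(KincommError):
    """Input data violates a structural invariant (duplicate pair, self-pair,
    asymmetric or negative weights, ...)."""


class AliasConflictError(ValidationError):
    """Alias merging produced duplicate pairs with unequal z-scores."""


class EmptyNetworkError(KincommError):
    """No edges survive the sign filter for the requested treatment."""


class DegenerateNetworkError(KincommError):
    """The network has zero total weight; no null model is defined."""


class CoverageError(KincommError):
    """A partition (or candidate set) does not cover the required node set."""


class SizeError(KincommError):
    """Problem too large for the exhaustive oracle."""


class NonConvergenceError(KincommError):
    """Consensus co-classification failed to become binary within the
    iteration budget.  Carries the last matrix for inspection."""

    def __init__(self, message, last_matrix=None):
        super().__init__(message)
        self.last_matrix = last_matrix


class ConfigError(KincommError):
    """Pipeline configuration is missing or inconsistent."""


class PipelineError(KincommError):
    """A pipeline stage failed; wraps the stage name and the original error."""

    def __init__(self, stage, original):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original
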