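"""Exception hierarchy shared across the pipeline."""


class SigresError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SigresError):
    """A file does not conform to its declared format (names the offending line)."""


class ValidationError(SigresError):
    """An in-memory object violates a structural invariant."""


class DegenerateSignalError(SigresError):
    """Treated profile coincides with the control mean: no direction exists."""


class DegenerateConsistencyError(SigresError):
    """Replicate directions cancel: the batch-average direction is undefined."""


class InsufficientControlsError(SigresError):
    """Fewer than two vehicle-control wells on a plate."""


class InsufficientReplicatesError(SigresError):
    """An operation requires at least two replicates."""
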