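"""Exception taxonomy.

Every error raised on a contract violation derives from :class:`N400LinkError`
so callers can distinguish scientific-contract failures from programming bugs.
"""


class N400LinkError(Exception):
    """Base class for all package errors."""


class InvalidInputError(N400LinkError):
    """An input violates a documented precondition (e.g. empty word)."""


class BackendContractError(N400LinkError):
    """A scoring backend returned something a conditional LM never may
    (positive or non-finite log-probability, non-normalized distribution)."""


class ValidationError(N400LinkError):
    """A table-driven artifact (mock LM, embedding file) failed validation."""


class DegenerateInputError(N400LinkError):
    """Input is formally valid but carries no usable information
    (constant vector, zero-norm embedding, all-equal AICs)."""


class SchemaError(N400LinkError):
    """A trial/stimulus table is missing a declared column."""


class DesignError(N400LinkError):
    """A regression design cannot be built or is degenerate."""


class RankDeficiencyError(DesignError):
    """The fixed-effect design matrix is not full rank."""


class NotNestedError(N400LinkError):
    """Likelihood-ratio test requested for non-nested models."""


class InsufficientDataError(N400LinkError):
    """Too few observations survive filtering to compute the statistic."""


class MissingItemsError(N400LinkError):
    """One or more stimulus items could not be scored by a backend."""

    def __init__(self, items, message=None):
        self.items = list(items)
        super().__init__(message or f"unscorable items: {self.items}")


class MetricOverflowError(N400LinkError):
    """e^(S^0.6) overflowed for one or more items."""

    def __init__(self, items, message=None):
        self.items = list(items)
        super().__init__(message or f"metric overflow for items: {self.items}")


class ConfigError(N400LinkError):
    """A run configuration is inconsistent or incomplete."""
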