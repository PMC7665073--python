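"""Exception hierarchy shared across the package."""


class AlgafeedError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(AlgafeedError, ValueError):
    """An argument violates a documented precondition."""


class UndefinedMetricError(AlgafeedError, ArithmeticError):
    """A metric is mathematically undefined for the given data.

    Raised e.g. for FCR with non-positive weight gain: tanks that lost
    biomass are surfaced explicitly rather than silently dropped.
    """


class SchemaError(AlgafeedError, ValueError):
    """A tabular input does not conform to its declared schema."""
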