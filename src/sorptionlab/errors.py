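"""Exception hierarchy for sorptionlab."""


class SorptionLabError(Exception):
    """Base class for all package errors."""


class EvaluationDomainError(SorptionLabError, ValueError):
    """A model was evaluated outside its mathematical domain."""


class InvalidParameterError(SorptionLabError, ValueError):
    """Parameter values violate a model's constraints."""


class InvalidProtocolError(SorptionLabError, ValueError):
    """A measurement-protocol setting (grid, range) is infeasible."""


class InvalidTruthError(SorptionLabError, ValueError):
    """A synthetic ground-truth configuration produces invalid moisture values."""


class InitializationError(SorptionLabError, RuntimeError):
    """Closed-form initialization failed (caller may fall back to GA)."""


class BoundsError(SorptionLabError, ValueError):
    """Search bounds admit no feasible candidate."""


class UnidentifiableError(SorptionLabError, ValueError):
    """A parameter cannot be estimated from the supplied design."""


class DegenerateInputError(SorptionLabError, ValueError):
    """A statistical test received degenerate input (constant vector, tiny group)."""


class SchemaError(SorptionLabError, ValueError):
    """Tabular input does not match the expected schema."""
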