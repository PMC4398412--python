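"""Exception hierarchy for creolang."""


class CreolangError(Exception):
    """Base class for all creolang errors."""


class InvalidPopulationError(CreolangError):
    """Population counts admit no dynamics (e.g. no Mulattos or Bozals)."""


class TopologyViolationError(CreolangError):
    """An interaction violated the contact topology (European hearer)."""


class InvariantViolationError(CreolangError):
    """An internal state invariant was broken (e.g. empty repertoire)."""


class StateSpaceTooLargeError(CreolangError):
    """Exact-chain enumeration would exceed the tractability guard."""


class InternalConsistencyError(CreolangError):
    """Probability mass unaccounted for in the exact transition matrix."""


class InvalidPointError(CreolangError):
    """A demographic point cannot be realized as valid integer counts."""


class SchemaError(CreolangError):
    """A census table is missing required columns."""


class EmptyInputError(CreolangError):
    """An input table contains no rows."""


class UnclassifiableError(CreolangError):
    """A census record has no Black population, so (x, y) is undefined."""


class EmptyEvaluationError(CreolangError):
    """No census record carries an observed-creole label."""


class GenerationError(CreolangError):
    """The synthetic-census generator cannot satisfy the requested margin."""


class ConfigError(CreolangError):
    """A run configuration failed validation."""
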