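"""Exception hierarchy for the evaluation pipeline.

Every error raised by the library derives from :class:`HeattolError`, so
callers (and the CLI) can catch one type.  Subclasses mark the contract
that was violated; messages always name the offending genotype, index,
row or component.
"""


class HeattolError(ValueError):
    """Base class for all pipeline errors."""


class FormatError(HeattolError):
    """Malformed input file: missing columns, non-numeric values."""


class DuplicateKeyError(HeattolError):
    """Two rows share a (genotype, index, condition, replicate) key."""


class ConditionError(HeattolError):
    """Condition label outside the CK/HS enumeration."""


class IncompletePairError(HeattolError):
    """A (genotype, index) cell is missing its CK or HS counterpart."""


class DomainError(HeattolError):
    """Value outside the mathematical domain (e.g. CK mean <= 0)."""


class DegenerateIndexError(HeattolError):
    """An index column is constant across genotypes (zero variance)."""


class DegenerateComponentError(HeattolError):
    """A component's scores are constant across genotypes (Xmax == Xmin)."""


class MissingIndexError(HeattolError):
    """A required index is absent from the supplied coefficients."""


class ConfigError(HeattolError):
    """Analysis or simulation configuration violates an invariant."""


class StageError(HeattolError):
    """Pipeline stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
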