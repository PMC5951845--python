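"""Exception and warning types shared across the package."""


class NestevoError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(NestevoError, ValueError):
    """A parameter violates its documented precondition."""


class InputError(NestevoError, ValueError):
    """Input data are malformed or mutually inconsistent (e.g. mixed tip sets)."""


class MissingTaxonError(InputError):
    """A tree tip has no corresponding record in the character matrix."""


class DuplicateRecordError(InputError):
    """Two records share the same family label."""


class VocabularyError(InputError):
    """A state label is not part of the character's vocabulary, or a
    missing-data family carries states."""


class UndefinedStatisticError(NestevoError, ValueError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class InsufficientSamplesError(NestevoError, ValueError):
    """Too few MCMC samples to compute the requested summary."""


class InsufficientChainsError(NestevoError, ValueError):
    """A multi-chain diagnostic was requested on fewer than two chains."""


class AbsentCladeError(NestevoError, KeyError):
    """A monitored clade is not present in any sampled tree."""


class WrongModelError(NestevoError, ValueError):
    """A summary was requested on a trace produced under an incompatible model."""


class DegenerateTraitWarning(UserWarning):
    """A binary trait shows only one observed state; contingent rates are
    unidentifiable."""


class DroppedReplicateWarning(UserWarning):
    """Null-model replicates were dropped (e.g. zero-variance simulated
    distance matrices)."""


class TuningWarning(UserWarning):
    """Proposal tuning ended outside the target acceptance band."""
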