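"""Exception hierarchy shared across the package."""


class OccucodeError(Exception):
    """Base class for all errors raised by occucode."""


class InvalidCodeError(OccucodeError, ValueError):
    """A raw code string cannot be parsed under the given scheme."""


class NotCodableAtLevelError(OccucodeError, ValueError):
    """A code contains a placeholder inside the requested level prefix."""


class ConfigurationError(OccucodeError, ValueError):
    """Invalid configuration (unknown language tag, malformed scheme file, ...)."""


class DataError(OccucodeError, ValueError):
    """Input data violates a precondition (misaligned lists, out-of-range values)."""


class DegenerateSplitError(OccucodeError, ValueError):
    """Too few records to populate every partition of a dataset split."""


class DegenerateModelError(OccucodeError, ValueError):
    """Training data does not support a model (e.g. a single outcome class)."""


class InsufficientDataError(OccucodeError, ValueError):
    """A statistical routine needs more observations per group."""


class MissingKeyError(OccucodeError, KeyError):
    """Strict-policy JEM lookup for a code absent from the matrix."""


class UndefinedStatisticError(OccucodeError, ValueError):
    """A statistic is undefined for the given input (e.g. tau on constants)."""


class InternalContractError(OccucodeError, RuntimeError):
    """A component violated an internal interface contract."""
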