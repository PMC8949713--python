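"""Exception hierarchy shared across the package."""


class BoutscanError(Exception):
    """Base class for all package errors."""


class SchemaError(BoutscanError):
    """An input file is missing required columns or has an unusable layout."""


class DataError(BoutscanError):
    """An input file parses but violates a data invariant (duplicates, etc.)."""


class InputError(BoutscanError, ValueError):
    """A function argument violates a precondition."""


class UndefinedStatisticError(BoutscanError):
    """A statistic is undefined for the given input (e.g. constant vector)."""


class UndefinedSpectrumError(BoutscanError):
    """A bout spectrum was requested over zero valid days."""


class SimulationError(BoutscanError):
    """The simulator could not realise the requested configuration."""
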