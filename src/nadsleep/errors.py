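"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: InputError -> 2, ConfigurationError -> 3,
InsufficientDataError -> 4.
"""


class NadSleepError(Exception):
    """Base class for all package errors."""


class InputError(NadSleepError):
    """Malformed or inconsistent input data (missing channels, bad events...)."""


class ConfigurationError(NadSleepError):
    """Invalid configuration or parameter value."""


class InsufficientDataError(NadSleepError):
    """Too little data to compute the requested quantity."""


class GenerationError(NadSleepError):
    """Synthetic-data generation could not satisfy its constraints."""


class DesignError(NadSleepError):
    """Statistical design invalid (unbalanced cells, missing factor levels)."""


class DegenerateInputError(NadSleepError):
    """Statistic undefined on the given input (e.g. zero variance)."""
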