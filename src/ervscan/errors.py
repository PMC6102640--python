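"""Exception taxonomy shared across the package.

`InputError` maps to CLI exit code 2, `DegenerateStatisticError` to exit
code 3 when warnings-as-errors mode is enabled.
"""


class ErvscanError(Exception):
    """Base class for all package errors."""


class InputError(ErvscanError, ValueError):
    """Malformed or inconsistent input files / parameters."""


class ConfigError(ErvscanError, ValueError):
    """Invalid configuration (bad window, empty reference, ...)."""


class DegenerateStatisticError(ErvscanError, RuntimeError):
    """A statistic could not be computed (empty group, zero variance, ...)."""
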