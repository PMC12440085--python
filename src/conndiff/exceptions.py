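"""Exception hierarchy.

``ValidationError`` signals bad user input (malformed tables, out-of-range
values, inconsistent designs) and maps to CLI exit code 2; every other
exception is a runtime failure and maps to exit code 1.
"""


class ConndiffError(Exception):
    """Base class for all package errors."""


class ValidationError(ConndiffError, ValueError):
    """Invalid input data or configuration."""


class ConfigError(ValidationError):
    """Invalid configuration value (bad alpha, threshold, choice key...)."""
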