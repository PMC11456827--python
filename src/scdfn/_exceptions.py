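"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: usage/parameter errors -> 2,
input/validation errors -> 3, numerical failures -> 4.
"""


class ScdfnError(Exception):
    """Base class for all package errors."""


class ParameterError(ScdfnError, ValueError):
    """An argument violates a precondition (bad k, bad flag combination...)."""


class InputError(ScdfnError, OSError):
    """A required input file is missing or unreadable."""


class ValidationError(ScdfnError, ValueError):
    """Input data violates a contract (negative counts, mismatched ids...)."""


class NumericalError(ScdfnError, ArithmeticError):
    """Non-finite values appeared during computation."""


class ConfigurationError(ScdfnError, ValueError):
    """Model/data shapes or settings are inconsistent."""
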