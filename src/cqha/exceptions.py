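"""Exception hierarchy.

``InputError`` covers malformed or inconsistent user inputs (CLI exit
code 2), ``NumericalError`` covers fit/minimization failures (exit code 3).
"""


class CqhaError(Exception):
    """Base class for all package errors."""


class InputError(CqhaError):
    """Malformed, missing, or inconsistent input data."""


class NumericalError(CqhaError):
    """A numerical procedure failed to converge or produced invalid output."""
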