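"""Exception hierarchy.

``UsageError`` maps to exit code 1 at the command line, ``DataError`` to 2.
"""


class IntroSpectError(Exception):
    """Base class for all package errors."""


class UsageError(IntroSpectError):
    """Invalid invocation: bad flags, inconsistent configuration."""


class DataError(IntroSpectError):
    """Malformed or empty input data."""
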