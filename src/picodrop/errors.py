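"""Exception hierarchy shared across the package.

Every CLI entry point maps these onto distinct, machine-parseable exit
messages; library callers can catch :class:`PicodropError` to get all of
them at once.
"""


class PicodropError(Exception):
    """Base class for all errors raised by this package."""


class DomainError(PicodropError, ValueError):
    """An argument is outside the mathematical domain of an operation
    (negative density, non-positive diameter, out-of-range ANI, ...)."""


class ConfigError(PicodropError, ValueError):
    """A configuration value or key is invalid or unknown."""


class ParseError(PicodropError, ValueError):
    """A file could not be parsed; the message names the file and,
    where possible, the offending line."""
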