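"""Exception hierarchy.

The CLI maps these onto distinct exit codes (input errors 2, configuration
errors 3, anything else 1), so library code should raise the most specific
class that applies.
"""


class SwingRNAError(Exception):
    """Base class for all package errors."""


class InputError(SwingRNAError, ValueError):
    """Malformed user-supplied data (sequences, tables, structures)."""


class ConfigError(SwingRNAError, ValueError):
    """Inconsistent or infeasible configuration."""


class DotBracketError(InputError):
    """Unparseable dot-bracket text; carries the offending position."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class ConstantInputError(InputError):
    """A correlation was requested on a zero-variance vector."""


class FixtureError(SwingRNAError):
    """Unknown fixture name or checksum mismatch."""
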