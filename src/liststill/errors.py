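"""Exception hierarchy.

Input-domain problems (a number outside its valid range) are distinguished
from configuration problems (a referenced field that does not exist) and from
file-level problems so callers and the CLI can report each distinctly.
"""


class ListStillError(Exception):
    """Base class for all package errors."""


class InputDomainError(ListStillError, ValueError):
    """A numeric argument lies outside its mathematical domain."""


class ConfigurationError(ListStillError, KeyError):
    """A profile/scenario/registry references a field that is not supplied."""

    def __str__(self) -> str:  # KeyError quotes its message; undo that
        return str(self.args[0]) if self.args else ""


class ParseError(ListStillError):
    """A config file could not be parsed at all (malformed YAML/JSON)."""


class SchemaError(ListStillError):
    """A config file parsed but is missing or mistyping required fields."""


class InvariantViolation(ListStillError):
    """A config file parsed and matched the schema but violates an invariant."""
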