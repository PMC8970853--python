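"""Shared exception types."""


class IcuPriorError(Exception):
    """Base class for all package errors."""


class ConfigError(IcuPriorError, ValueError):
    """A configuration value is invalid; the message names the field."""


class SchemaError(IcuPriorError, ValueError):
    """A table is missing required columns or channels."""


class ParseError(IcuPriorError, ValueError):
    """A cell could not be parsed; the message carries the row number."""


class IntegrityError(IcuPriorError, ValueError):
    """Referential integrity between tables is violated."""


class StateError(IcuPriorError, RuntimeError):
    """An operation was called before its prerequisites were met."""
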