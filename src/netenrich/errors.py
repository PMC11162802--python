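"""Exception types shared across netenrich modules."""


class NetenrichError(Exception):
    """Base class for all netenrich errors."""


class SchemaError(NetenrichError):
    """A table is missing required columns or uses an unknown schema."""


class ValidationError(NetenrichError):
    """A row or value violates an invariant of its domain type."""


class UsageError(NetenrichError):
    """An operation was called with an invalid option or parameter."""
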