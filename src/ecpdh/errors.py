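"""Exception types shared across the package."""


class EcpdhError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(EcpdhError, ValueError):
    """A table, record or block does not match the expected feature schema."""


class ParseError(EcpdhError, ValueError):
    """A feature-table file could not be parsed; message names row/column."""


class InvalidInputError(EcpdhError, ValueError):
    """An operation received arguments violating its preconditions."""


class DegenerateDataError(EcpdhError, ValueError):
    """The data are degenerate for the requested operation (e.g. a single
    class where two are required, or too few minority samples to
    interpolate)."""
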