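"""Exception hierarchy shared across the package.

All errors derive from :class:`EbvarError` so callers (and the CLI) can map
any package failure to a single exit path while still distinguishing
validation problems (exit 2) from estimation failures (exit 3).
"""


class EbvarError(Exception):
    """Base class for all package errors."""


class SchemaError(EbvarError):
    """An input table is missing a required column or has a malformed header."""


class ParseError(EbvarError):
    """A cell could not be parsed; message carries the 1-based row number."""


class IntegrityError(EbvarError):
    """Structural invariant violated (duplicate keys, timestamp gaps...)."""


class DomainError(EbvarError):
    """A value is outside the mathematical domain of an operation."""


class EstimationError(EbvarError):
    """Model fitting failed (singular design, non-convergence)."""
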