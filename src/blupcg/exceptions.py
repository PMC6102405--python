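"""Exception hierarchy for blupcg.

All package errors derive from :class:`BlupcgError` so callers (and the CLI)
can catch everything from one root.
"""


class BlupcgError(Exception):
    """Root of all blupcg errors."""


class ParseError(BlupcgError):
    """A file could not be parsed; the message names the offending line."""


class ConfigurationError(BlupcgError):
    """The parameter file or model specification is inconsistent."""


class FormatError(BlupcgError):
    """A data file violates its format contract."""


class DimensionError(BlupcgError):
    """An index or matrix order is out of range."""


class DataError(BlupcgError):
    """A record is unusable for the declared model (e.g. missing covariate)."""


class DegenerateInputError(BlupcgError):
    """Input is degenerate for the requested operation (e.g. all-monomorphic loci)."""


class NumericalError(BlupcgError):
    """A factorization or iterative computation failed numerically."""
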