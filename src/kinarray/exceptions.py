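"""Exception hierarchy for kinarray.

All validation failures derive from :class:`KinarrayError` so callers can
distinguish data problems from programming errors, while each concrete class
still subclasses the matching builtin (``ValueError``/``KeyError``-style
semantics are preserved for idiomatic ``except`` clauses).
"""


class KinarrayError(Exception):
    """Base class for all kinarray-specific errors."""


class SchemaError(KinarrayError, ValueError):
    """An input table is missing required columns or has malformed values."""


class ReferentialError(KinarrayError, ValueError):
    """A measurement references a sample absent from the annotation table."""


class UniquenessError(KinarrayError, ValueError):
    """Duplicate measurement keys (same spot coordinates twice)."""


class PairingError(KinarrayError, ValueError):
    """A with-inhibitor measurement has no without-inhibitor partner on its chip."""


class CompletenessError(KinarrayError, ValueError):
    """A sample/peptide cell has no replicates under the requested condition."""


class NoDiscoveriesError(KinarrayError, ZeroDivisionError):
    """Plug-in FDR is undefined because no peptide was called significant."""
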