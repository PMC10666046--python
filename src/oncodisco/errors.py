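"""Exception hierarchy.

Argument problems raise :class:`ArgumentError` (a ``ValueError``), data
problems (bad matrices, missing references, degenerate labels) raise
:class:`DataError`, so callers can distinguish "you called it wrong" from
"your data cannot support this operation".
"""


class OncodiscoError(Exception):
    """Base class for all package errors."""


class ArgumentError(OncodiscoError, ValueError):
    """Invalid argument (non-positive count, out-of-range fraction, ...)."""


class DataError(OncodiscoError, ValueError):
    """Input data violates a precondition (missing gene, degenerate labels)."""


class StratificationError(DataError):
    """A cross-validation fold cannot contain both classes."""


class EmbeddingLookupError(OncodiscoError, KeyError):
    """Token absent from an embedding table."""


class SmilesParseError(DataError):
    """A SMILES string could not be parsed; message names the input."""


class ConfigError(OncodiscoError, ValueError):
    """Pipeline configuration failed validation."""
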