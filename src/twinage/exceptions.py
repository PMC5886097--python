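"""Exception hierarchy.

Every reader rejects bad input with an error naming the offending file,
row or field rather than silently coercing.
"""


class TwinageError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TwinageError):
    """An inconsistent configuration value; message names the field."""


class ValidationError(TwinageError):
    """An input table violated an invariant; message names file/row/field."""


class DegenerateFeatureError(TwinageError):
    """A feature cannot be analysed (constant, too short); caller may skip it."""


class ContractError(TwinageError):
    """An operation was called outside its contract (e.g. REML fits in an LRT)."""
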