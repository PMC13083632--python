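"""Exception and warning hierarchy.

Every error raised by the library derives from :class:`TablignError`, so
callers (including the CLI) can distinguish data errors from programming
errors with a single ``except`` clause.
"""


class TablignError(Exception):
    """Base class for all library errors."""


class DuplicateColumnError(TablignError):
    """A table header contains the same column name more than once."""


class EmptyTableError(TablignError):
    """A table has no columns at all."""


class EmptySchemaError(TablignError):
    """A target schema offers no attributes to match against."""


class UnknownMethodError(TablignError):
    """A matcher or value-matching method name is not registered."""


class UnknownStandardError(TablignError):
    """A data-model standard name is not registered."""


class UnknownAttributeError(TablignError):
    """An attribute name does not exist in a standard or schema."""


class MissingValuesError(TablignError):
    """A value matcher needs permissible values the target does not provide."""


class NotNumericError(TablignError):
    """A numeric operation was requested on a non-numeric column."""


class ScorerContractError(TablignError):
    """A user-supplied similarity scorer returned a value outside [0, 1]."""


class EncoderError(TablignError):
    """A text encoder backend failed to produce embeddings."""


class AdapterError(TablignError):
    """A chat adapter backend failed or returned an unusable response."""


class ManyToOneError(TablignError):
    """Two distinct source attributes map to the same target attribute."""


class MissingSourceAttributeError(TablignError):
    """A mapping references a source attribute absent from the input table."""


class UnresolvedRoutineError(TablignError):
    """A custom mapper routine name is not registered at materialization."""


class SpecFormatError(TablignError):
    """A harmonization-specification document is malformed."""


class NonConvergenceWarning(UserWarning):
    """Similarity flooding hit its iteration cap before the fixpoint."""


class InsufficientDataWarning(UserWarning):
    """A column has too few non-missing values for a distribution comparison."""
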