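"""Exception taxonomy shared by all stages.

The CLI maps these onto exit codes: usage errors -> 1,
:class:`DataValidationError` -> 2, :class:`NumericError` -> 3.
"""


class HepamarkError(Exception):
    """Base class for all pipeline errors."""


class DataValidationError(HepamarkError):
    """An input table or configuration violates a documented invariant."""


class NumericError(HepamarkError):
    """A numeric operation cannot be carried out (e.g. zero variance)."""
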