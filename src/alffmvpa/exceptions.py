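"""Exception hierarchy.

All argument problems raise :class:`InvalidArgumentError` (a ``ValueError``),
so callers can catch one type; file/shape problems raise
:class:`VolumeFormatError`; statistically degenerate inputs (zero variance,
constant vectors) raise :class:`DegenerateDataError`.
"""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class VolumeFormatError(InvalidArgumentError):
    """A volume file or array does not have the expected layout."""


class DegenerateDataError(InvalidArgumentError):
    """Input is statistically degenerate (e.g. zero variance)."""
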