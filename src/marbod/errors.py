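"""Exception hierarchy.

All package errors derive from :class:`MarbodError` so callers can catch one
base class. I/O-shape problems (bad header, unparseable cell) raise
:class:`FormatError`; semantically invalid but well-formed inputs raise
:class:`ValidationError`.
"""


class MarbodError(Exception):
    """Base class for all marbod errors."""


class FormatError(MarbodError):
    """A file does not conform to the documented CSV dialect."""


class ValidationError(MarbodError):
    """Well-formed input that violates a domain invariant."""


class ExtrapolationError(MarbodError):
    """A value was requested outside a bottle's observed time range."""


class DegenerateTrialError(MarbodError):
    """The positive control carries no usable signal (corrected BOD <= 0)."""
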