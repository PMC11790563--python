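"""Exception hierarchy for cultfit.

All errors raised on bad user input derive from :class:`CultFitError` so callers
can catch one base class; the subclasses distinguish malformed files, invalid
values, unusable parameters and analyses attempted on too little data.
"""


class CultFitError(Exception):
    """Base class for all cultfit errors."""


class FormatError(CultFitError, ValueError):
    """A file does not conform to the expected dialect/layout."""


class ValidationError(CultFitError, ValueError):
    """Well-formed input carries invalid values (names the offending item)."""


class ParameterError(CultFitError, ValueError):
    """An argument is outside its admissible range or combination."""


class InsufficientDataError(CultFitError, ValueError):
    """Too few observations to run the requested computation."""
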