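"""Exception hierarchy for nupeval.

All user-facing failures derive from :class:`NupevalError` so CLI code can
catch one base class and turn it into a nonzero exit with a readable message.
"""


class NupevalError(Exception):
    """Base class for all nupeval errors."""


class ValidationError(NupevalError, ValueError):
    """Raised when input data violate a documented domain constraint."""


class ScaleTypeError(NupevalError, TypeError):
    """Raised when a raw value of the wrong kind is scored against a scale
    (e.g. a boolean against a numeric rubric attribute)."""
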