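"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`HSPScreenError` so callers (and the CLI) can catch one base class.
"""


class HSPScreenError(ValueError):
    """Base class for all hspscreen errors."""


class ValidationError(HSPScreenError):
    """Invalid value, unit or structure in user-supplied input."""


class DegenerateDataError(HSPScreenError):
    """Input is structurally valid but carries no usable signal
    (e.g. zero variance in swelling, all solvents identical)."""


class EstimationFailureError(HSPScreenError):
    """The R^2 maximization found no candidate with the required
    negative swelling-distance correlation."""


class MissingValueError(HSPScreenError):
    """A required value (polymer HSP, interaction radius, solvent entry)
    was not supplied and has no shipped default."""
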