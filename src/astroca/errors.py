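"""Exception hierarchy shared across the package."""


class AstrocaError(Exception):
    """Base class for all astroca errors."""


class ValidationError(AstrocaError, ValueError):
    """An input object or parameter failed validation."""


class PlacementError(AstrocaError):
    """Cells could not be placed in the requested frame geometry."""


class FitRejectedError(AstrocaError):
    """A model fit did not meet its quality requirements."""
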