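"""Exception hierarchy shared across the pipeline."""


class GlidekinError(Exception):
    """Base class for all package errors."""


class ValidationError(GlidekinError, ValueError):
    """Input violates a documented invariant (units, signs, monotone time...)."""


class FormatError(GlidekinError, ValueError):
    """A file does not match the expected on-disk layout."""


class IntegrationError(GlidekinError, RuntimeError):
    """The trajectory integrator reached an invalid state."""


class InsufficientPeaksError(GlidekinError, RuntimeError):
    """Too few oscillation peaks to estimate a damping ratio."""
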