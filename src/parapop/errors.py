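"""Exception hierarchy shared across the package."""


class ParapopError(Exception):
    """Base class for all package errors."""


class ValidationError(ParapopError):
    """Input violates a documented precondition or invariant."""


class VcfFormatError(ParapopError):
    """VCF cannot be parsed (malformed header, missing GT field, ...)."""


class AnnotationMissingError(VcfFormatError):
    """ANN annotations were required but are absent from the VCF."""


class DegenerateModelError(ParapopError):
    """A demographic model produces no expected polymorphism."""
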