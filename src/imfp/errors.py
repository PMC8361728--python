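"""Exception and warning types shared across the package."""


class ImfError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ImfError, ValueError):
    """An input object violates a documented invariant."""


class ParseError(ImfError, ValueError):
    """A text table could not be parsed; the message names the offending line."""


class RangeError(ImfError, ValueError):
    """A requested wavenumber range falls outside the available grid."""


class DegenerateReferenceError(ImfError, ValueError):
    """The water reference carries no derivative signal in the fitting window,
    so the subtraction scale is undefined."""


class DegenerateNormalizationError(ImfError, ValueError):
    """A protein has no usable reference intensities to normalize against."""


class ComputationError(ImfError, RuntimeError):
    """A numerical routine failed to produce a usable result."""


class NegativeScaleWarning(UserWarning):
    """The optimal water-subtraction scale came out negative, which usually
    signals a corrupted reference measurement."""


class CollinearLibraryWarning(UserWarning):
    """The component library is nearly rank-deficient; concentration estimates
    are unstable."""


class ConstantFeatureWarning(UserWarning):
    """A zero-variance feature was dropped before classification."""
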