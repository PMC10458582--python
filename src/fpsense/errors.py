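"""Exception hierarchy for fpsense.

All toolkit errors derive from :class:`FPSenseError` so callers (and the CLI)
can catch one base class.
"""


class FPSenseError(Exception):
    """Base class for all fpsense errors."""


class InvalidInputError(FPSenseError, ValueError):
    """An argument violates a precondition (non-positive wavelength, empty
    frame sequence, bad parameter value, ...)."""


class InvalidGeometryError(FPSenseError, ValueError):
    """Physically impossible geometry, e.g. cavity longer than the gauge
    length of the mounting."""


class GridResolutionError(FPSenseError):
    """The wavelength grid is too coarse to resolve the interference fringes
    of the requested cavity."""


class InsufficientFringesError(FPSenseError):
    """Fewer than two interference maxima were found; the fringe order (and
    hence the absolute cavity length) cannot be determined."""


class AmbiguousOrderError(FPSenseError):
    """The fringe-order estimate falls too far from an integer to be trusted."""


class InvalidWindowError(FPSenseError):
    """A baseline-noise window crosses an activation step or holds too few
    samples."""


class ReconciliationError(FPSenseError):
    """Detected activation steps cannot be matched one-to-one to the
    activation schedule."""


class ConfigError(FPSenseError):
    """An experiment configuration is internally inconsistent or produces
    signals outside the demodulable range."""


class FormatError(FPSenseError):
    """A data file violates its format contract (non-monotone wavelengths,
    missing columns, NaNs); the message names the offending line."""
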