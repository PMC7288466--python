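"""Exception hierarchy.

Every error raised on bad scientific input derives from :class:`OriminError`
so callers (and the CLI) can distinguish data problems from bugs.
"""


class OriminError(ValueError):
    """Base class for all input/consistency errors raised by orimin."""


class DomainError(OriminError):
    """An input lies outside the mathematical domain of an operation."""


class InconsistentObservationError(OriminError):
    """Two observations of the same population contradict each other.

    The message names the observations that conflict, so miscounted
    microscopy data can be traced back to its source.
    """


class LabelingTooLowError(InconsistentObservationError):
    """The labeled fraction is too small to be consistent with any S >= 0."""


class UnsupportedConfigurationError(OriminError):
    """A simulation configuration outside the closed-form model's validity."""


class FormatError(OriminError):
    """A karyotype / counts file could not be parsed."""


class DegenerateTrendError(OriminError):
    """A trend line unusable for a slope ratio (non-positive slope)."""
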