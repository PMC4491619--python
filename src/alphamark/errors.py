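"""Exception hierarchy.

Every error raised by the package derives from :class:`AlphamarkError` so
callers (and the pipeline driver) can distinguish pipeline failures from
programming errors.
"""


class AlphamarkError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(AlphamarkError):
    """A synthetic-data specification violates its invariants."""


class GenerationError(AlphamarkError):
    """Cohort generation could not realize the requested targets."""


class FormatError(AlphamarkError):
    """An input file could not be interpreted as a recording."""


class EmptyInputError(AlphamarkError):
    """An operation received no usable data (e.g. zero kept epochs)."""


class MontageError(AlphamarkError):
    """A requested channel label is not present in the recording."""


class AnchorError(AlphamarkError):
    """Anchor frequencies are missing, degenerate, or out of order."""


class BandError(AlphamarkError):
    """A frequency band contains no spectral bins on the analysis grid."""


class DesignError(AlphamarkError):
    """A statistical design is unbalanced or otherwise unusable."""


class NormError(AlphamarkError):
    """A normative regression is degenerate (too few controls, zero spread)."""


class ConfigError(AlphamarkError):
    """A pipeline configuration is invalid."""
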