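"""Exception hierarchy for ihcscore.

Every error raised by the library derives from :class:`IHCScoreError` so
callers (and the CLI) can catch one base class.
"""


class IHCScoreError(Exception):
    """Base class for all ihcscore errors."""


class InvalidBackgroundError(IHCScoreError):
    """Background white level contains a zero (or otherwise invalid) channel."""


class DegenerateStainsError(IHCScoreError):
    """Stain matrix is singular or numerically non-invertible."""


class EmptyInputError(IHCScoreError):
    """An operation received an empty image or empty list."""


class NoScoreablePixelsError(IHCScoreError):
    """Every pixel fell in the excluded bright range; nothing to grade."""


class InvalidSpecError(IHCScoreError):
    """Synthetic-image region specification is inconsistent."""


class DegenerateTableError(IHCScoreError):
    """Contingency table has a zero marginal, or kappa is undefined."""


class ConfigError(IHCScoreError):
    """Run configuration failed validation; message names the field."""
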