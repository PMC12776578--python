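"""Exception hierarchy.

Everything raised deliberately by glassdyn derives from :class:`GlassdynError`
so the CLI can translate any domain failure into a one-line message and a
nonzero exit code.
"""


class GlassdynError(Exception):
    """Base class for all glassdyn errors."""


class SchemaError(GlassdynError):
    """An input table is missing a required column or has an ambiguous one."""


class DataError(GlassdynError):
    """An input table violates a data invariant (e.g. non-monotone frequency)."""


class DomainError(GlassdynError, ValueError):
    """A parameter value is outside the mathematical domain of a model."""


class FitError(GlassdynError):
    """A fit cannot be attempted (too few points, singular design, ...)."""


class TruncatedPeakError(GlassdynError):
    """A peak required for a shape analysis lies at the window edge."""


class OverRecoveryError(GlassdynError):
    """Recovered enthalpy exceeds the equilibrium value at some time points."""

    def __init__(self, message, points=None):
        super().__init__(message)
        self.points = points or []


class FeatureNotFoundError(GlassdynError):
    """An expected thermal feature (step or peak) is absent from the trace."""
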