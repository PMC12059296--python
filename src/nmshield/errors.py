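"""Exception hierarchy for nmshield.

All package-specific failures derive from :class:`ShieldingError` so callers
can catch one base class at the CLI boundary.
"""


class ShieldingError(Exception):
    """Base class for all nmshield errors."""


class UnknownNuclideError(ShieldingError, KeyError):
    """Requested radionuclide is not one of the four shipped nuclides."""


class UnknownMaterialError(ShieldingError, KeyError):
    """Requested material is not in the material table."""


class MissingArcherPairError(ShieldingError, KeyError):
    """No fitted transmission parameters exist for this nuclide/material pair."""


class UnknownAreaError(ShieldingError, KeyError):
    """Occupancy area key did not match any tabulated area."""


class DomainError(ShieldingError, ValueError):
    """An input is outside the physically meaningful domain (e.g. T > 1)."""


class GeometryError(ShieldingError):
    """Inconsistent or unsupported Monte Carlo geometry."""


class InsufficientHistoriesError(ShieldingError):
    """A Monte Carlo tally was empty; rerun with more histories."""


class DegenerateCurveError(ShieldingError, ValueError):
    """A transmission curve carries no attenuation information (all T = 1)."""


class TooFewPointsError(ShieldingError, ValueError):
    """Fewer data points than free parameters in the fit."""


class MismatchedCurveError(ShieldingError, ValueError):
    """Attempt to compare fits for different nuclide/material pairs."""


class ConfigError(ShieldingError, ValueError):
    """Malformed scenario or simulation configuration."""
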