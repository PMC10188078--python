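"""Exception hierarchy for layreq.

All domain errors derive from :class:`LayreqError` so callers can catch one
base class at pipeline boundaries.
"""


class LayreqError(Exception):
    """Base class for all layreq domain errors."""


class InvalidDesignError(LayreqError):
    """A trial design violates its structural constraints."""


class InvalidParameterError(LayreqError):
    """A simulation or model parameter set is internally inconsistent."""


class DataIntegrityError(LayreqError):
    """Raw records violate bookkeeping constraints (e.g. eggs > hen-days)."""


class UndefinedTraitError(LayreqError):
    """A trait is mathematically undefined for the given inputs."""


class IdentifiabilityError(LayreqError):
    """A model cannot be identified from the data provided."""


class ComparisonError(LayreqError):
    """Model fits on different data cannot be ranked against each other."""


class ConfigError(LayreqError):
    """A run configuration fails validation."""
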