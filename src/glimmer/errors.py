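"""Exception hierarchy for the glimmer package.

Every named error contract in the analysis surfaces as a distinct class so
callers (and the CLI) can react to schema problems, degenerate label sets and
configuration mistakes separately.
"""


class GlimmerError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpectrumError(GlimmerError):
    """A reflectance spectrum violates its invariants (grid or value range)."""


class EmptyBandError(GlimmerError):
    """A wavelength band contains no grid point of the spectrum."""


class GridMismatchError(GlimmerError):
    """Spectra expected to share a wavelength grid do not."""


class EmptyROIError(GlimmerError):
    """An ROI aggregate was requested over zero spectra."""


class ConfigError(GlimmerError):
    """Invalid configuration (index definitions, simulation settings, filters)."""


class ValidationError(GlimmerError):
    """An input value or table violates its declared domain."""


class SchemaError(ValidationError):
    """A cohort table is missing columns or contains malformed rows."""


class DegenerateLabelsError(GlimmerError):
    """A binary-truth analysis received labels from a single class."""


class EmptyInputError(GlimmerError):
    """An operation received an empty collection where at least one element is required."""


class EmptySubgroupError(GlimmerError):
    """A subgroup filter matched no cases."""
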