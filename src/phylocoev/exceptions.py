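"""Exception hierarchy shared across the package."""


class PhylocoevError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PhylocoevError):
    """A required column or field is absent from an input file."""


class ValidationError(PhylocoevError):
    """A value violates a declared invariant (range, integrality, uniqueness)."""


class ConfigError(PhylocoevError):
    """An option value is outside the set of recognized choices."""


class TreeError(PhylocoevError):
    """A tree is malformed: unparseable, unrooted, or missing branch lengths."""


class MatchingError(PhylocoevError):
    """Taxon labels required by a map are absent from one or more trees."""


class AlignmentError(PhylocoevError):
    """Row labels of a covariance matrix do not align with the data table."""


class KernelError(PhylocoevError):
    """A covariance matrix fails symmetry or positive-semidefiniteness checks."""


class DegenerateInputError(PhylocoevError):
    """Input is degenerate for the requested operation (all-zero distances, zero-depth tip, zero scale)."""


class StabilityError(PhylocoevError):
    """A selection matrix is singular or not stable (eigenvalues must have negative real part)."""


class ConvergenceWarning(UserWarning):
    """Sampler diagnostics exceeded thresholds (R-hat, divergences)."""
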