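"""Exception hierarchy.

Every raisable condition in the pipeline maps to one of these so callers can
distinguish bad configuration from bad data from non-estimable statistics.
"""


class CisregError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(CisregError):
    """A simulation or pipeline configuration field is out of range."""


class InvalidInputError(CisregError):
    """A scalar argument violates its documented domain."""


class AmbiguousInputError(CisregError):
    """Duplicate or conflicting records where at most one is allowed."""


class MissingAnnotationError(CisregError):
    """A required annotation (TSS, column, field) is absent."""


class InvalidAnnotationError(CisregError):
    """An annotation label is outside its configured vocabulary."""


class UndefinedCorrelationError(CisregError):
    """Correlation undefined (constant vector after masking)."""


class InvalidMotifError(CisregError):
    """A position weight matrix is malformed (e.g. zero column sums)."""


class DegenerateTableError(CisregError):
    """A contingency table has no information (zero margin or all-zero)."""


class InsufficientPoolError(CisregError):
    """Requested sample size exceeds the available pool."""


class InvalidGenotypeError(CisregError):
    """Genotype allele outside the locus alphabet."""


class MissingGenotypeError(CisregError):
    """A panel locus is not genotyped and imputation is disabled."""


class EmptyInputError(CisregError):
    """An operation received no usable records."""


class ModelUnavailableError(CisregError):
    """A genetic model's preconditions are unmet (e.g. no homozygous-risk
    subjects for a recessive fit)."""


class NonEstimableError(CisregError):
    """A model is formally specified but not estimable on these data
    (perfect separation, monotone partial likelihood)."""


class InvalidLabelError(CisregError):
    """A categorical label outside its vocabulary (e.g. treatment response)."""
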