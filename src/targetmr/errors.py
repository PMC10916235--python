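"""Exception hierarchy for targetmr.

Every stage raises a subclass of :class:`TargetMrError` so callers can
distinguish bad inputs (schema/validation), bad usage (wrong routing),
and statistical degeneracy (too few or collinear instruments).
"""


class TargetMrError(Exception):
    """Base class for all targetmr errors."""


class SchemaError(TargetMrError):
    """A required column or field is missing from an input table."""


class ValidationError(TargetMrError):
    """A field value violates a record invariant (reported with 1-based row)."""


class FormatError(TargetMrError):
    """A file is structurally malformed (e.g. non-square LD block)."""


class ParameterError(TargetMrError, ValueError):
    """A numeric parameter is outside its valid range."""


class UsageError(TargetMrError):
    """An operation was called in a way its contract forbids."""


class CoverageError(TargetMrError):
    """Required SNPs are absent from a companion dataset (LD panel, region)."""


class AnnotationError(TargetMrError):
    """A gene annotation needed by the operation is missing or incomplete."""


class InsufficientInstrumentsError(TargetMrError):
    """Fewer instruments than the estimator's minimum; recorded, not fatal."""


class EstimationError(TargetMrError):
    """Numerical degeneracy during estimation (zero exposure beta, collinearity)."""


class VocabularyError(TargetMrError):
    """A categorical field holds a value outside the controlled vocabulary."""


class ConsistencyError(TargetMrError):
    """Cross-table join inconsistency (e.g. coloc result for a gene absent from MR)."""
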