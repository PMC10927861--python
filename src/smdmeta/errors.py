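"""Exception hierarchy shared across the pipeline."""


class SmdMetaError(Exception):
    """Base class for all package errors."""


class SchemaError(SmdMetaError):
    """Input table is missing a required column or is otherwise malformed."""


class ValidationError(SmdMetaError):
    """A data row violates a field contract (unknown category, missing SD/SE)."""


class DomainError(SmdMetaError, ValueError):
    """An argument is outside the domain of an operation."""


class DegenerateComparisonError(DomainError):
    """Pooled SD is zero while the arm means differ: the SMD is undefined."""


class DegenerateDesignError(DomainError):
    """Meta-regression design matrix is rank-deficient (single-level moderator)."""
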