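"""Exception hierarchy for the agescan pipeline.

Every stage raises a subclass of :class:`AgescanError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class AgescanError(Exception):
    """Base class for all agescan errors."""


class InvalidSpecError(AgescanError, ValueError):
    """A simulation or analysis specification violates its invariants."""


class DimensionError(AgescanError, ValueError):
    """Row/column counts of two inputs that must align do not."""


class StateError(AgescanError, RuntimeError):
    """A phenotype table is in the wrong processing state for an operation
    (e.g. applying medication corrections twice)."""


class MonomorphicVariantError(AgescanError, ValueError):
    """The dosage vector is constant; no genetic effect is estimable."""


class CollinearityError(AgescanError, ValueError):
    """The regression design is rank deficient; carries the offending column."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"design matrix is rank deficient at column {column!r}")


class AlignmentError(AgescanError, ValueError):
    """Genotype and phenotype sources share no samples."""


class EmptyCohortError(AgescanError, ValueError):
    """A filter removed every individual."""


class EmptyStratumError(AgescanError, ValueError):
    """A requested stratum (age bin, sex, genotype category) has no samples."""


class SchemaError(AgescanError, ValueError):
    """A results file does not match the expected column schema."""
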