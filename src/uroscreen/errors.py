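"""Exception hierarchy shared across the package."""


class UroscreenError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(UroscreenError, ValueError):
    """A configuration object violates its invariants."""


class DegenerateHistogramError(UroscreenError, ValueError):
    """Histogram has a single populated bin; no threshold separates it."""


class SchemaError(UroscreenError, ValueError):
    """A file is syntactically valid but violates the expected schema."""


class ContractError(UroscreenError, TypeError):
    """A pluggable component does not satisfy its declared contract."""


class TrainingError(UroscreenError, RuntimeError):
    """Training entered an unrecoverable state (e.g. NaN loss)."""


class ShortfallError(UroscreenError, ValueError):
    """A sampling pool cannot satisfy the requested composition."""

    def __init__(self, message: str, deficient: str | None = None):
        super().__init__(message)
        self.deficient = deficient


class UndefinedMetricError(UroscreenError, ValueError):
    """A metric is undefined for the given inputs (e.g. single-class ROC)."""


class OutOfBoundsError(UroscreenError, ValueError):
    """A requested region lies entirely outside the slide."""
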