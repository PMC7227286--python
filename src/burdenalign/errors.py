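"""Exception hierarchy shared across the pipeline.

Every error raised by this package derives from :class:`BurdenAlignError`,
so callers can catch one type at the pipeline boundary while tests can
assert on the specific condition.
"""


class BurdenAlignError(Exception):
    """Base class for all package errors."""


class SchemaError(BurdenAlignError):
    """An input table is missing a required column or has an unusable header."""


class RowValidationError(BurdenAlignError):
    """A single input row violates a field-level constraint.

    Carries the offending row number (1-based, header excluded) when known.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class ConflictError(BurdenAlignError):
    """Duplicate key where uniqueness is required (e.g. cause_id)."""


class UnknownCountryError(BurdenAlignError):
    """A country code has no income-group assignment under the strict policy."""


class UndefinedRatioError(BurdenAlignError):
    """A ratio whose numerator and denominator are both zero (0/0)."""


class UndefinedShareError(BurdenAlignError):
    """A share requested over an empty scope (zero total weight)."""


class MissingBaselineError(BurdenAlignError):
    """A record's field-year has no citation baseline in the reference set."""


class ConfigError(BurdenAlignError):
    """A run or generator configuration is internally inconsistent."""
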