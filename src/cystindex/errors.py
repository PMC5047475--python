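"""Exception hierarchy for the cystindex pipeline.

Every error raised on a user-facing path derives from :class:`CystindexError`
so callers (and the CLI) can distinguish pipeline failures from bugs.
"""


class CystindexError(Exception):
    """Base class for all cystindex errors."""


class SchemaError(CystindexError):
    """A table is structurally unusable (e.g. the CI column is absent)."""


class DomainError(CystindexError):
    """A value violates a domain constraint (e.g. a negative biomarker level)."""


class UnknownVariableError(CystindexError, KeyError):
    """A requested variable is not part of the table's panel."""


class InsufficientDataError(CystindexError):
    """Too few complete pairs to fit anything (n < 3)."""


class DegeneratePredictorError(CystindexError):
    """The predictor is constant; no slope is identifiable."""


class FamilyInapplicableError(CystindexError):
    """A trendline family's preconditions fail for this series.

    During screening this is a signal, not a failure: the family is
    skipped and recorded as inapplicable.
    """


class EmptyCalculatorError(CystindexError):
    """No biomarker survived the screening gate; no calculator can be built."""


class DuplicateVariableError(CystindexError):
    """Two component equations claim the same variable."""


class IncompletePanelError(CystindexError):
    """A prediction panel is missing required component variables."""

    def __init__(self, missing):
        self.missing = tuple(missing)
        super().__init__(
            "panel is missing required variables: " + ", ".join(self.missing)
        )


class FixtureIntegrityError(CystindexError):
    """The packaged study table does not match its frozen reference copy."""


class ConfigError(CystindexError):
    """An invalid configuration value."""
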