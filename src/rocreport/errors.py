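"""Exception hierarchy shared by all rocreport modules."""


class RocReportError(Exception):
    """Base class for all errors raised by rocreport."""


class ColumnNotFoundError(RocReportError):
    """A named marker/outcome column is absent from the input table."""


class OutcomeCardinalityError(RocReportError):
    """The outcome column does not contain exactly two distinct labels."""


class MarkerParseError(RocReportError):
    """A marker cell could not be parsed as a number; identifies the row."""


class EmptyInputError(RocReportError):
    """The input file contains no data rows."""


class DegenerateDataError(RocReportError):
    """The data cannot support the requested analysis (single class,
    constant marker, all-degenerate contingency tables, ...)."""


class InsufficientDataError(RocReportError):
    """Too few observations for the requested statistic."""


class InfeasibleConstraintError(RocReportError):
    """No operating point satisfies the user's sensitivity/specificity bound."""


class TemplateError(RocReportError):
    """A report prompt template references an unknown placeholder."""


class RenderError(RocReportError):
    """Report rendering failed (e.g. a referenced figure file is missing)."""


class TransportConfigError(RocReportError):
    """The LLM transport is not configured (e.g. missing API key)."""
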