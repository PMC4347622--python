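"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: usage problems -> 2, data problems -> 3,
numeric failures during training/evaluation -> 4.
"""


class EnnscoreError(Exception):
    """Base class for all package-specific errors."""


class UsageError(EnnscoreError):
    """Invalid arguments or configuration (exit code 2)."""


class DataError(EnnscoreError):
    """Problems with input data files or tables (exit code 3)."""


class SchemaError(DataError):
    """A required column is missing or the column-role mapping is wrong."""


class TableParseError(DataError):
    """A cell could not be parsed; message names the row and column."""


class IntegrityError(DataError):
    """Duplicate identifiers or inconsistent records."""


class NumericError(EnnscoreError):
    """Non-finite values produced during fitting or scoring (exit code 4)."""


class UndefinedStatisticError(NumericError):
    """A correlation/regression statistic is undefined for the given input
    (e.g. a constant vector), raised instead of silently returning NaN."""
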