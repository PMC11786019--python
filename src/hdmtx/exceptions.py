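"""Exception hierarchy shared across the pipeline."""


class HdmtxError(Exception):
    """Base class for all package errors."""


class InvalidInputError(HdmtxError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(HdmtxError, ValueError):
    """Too few usable observations to run the requested computation."""


class SchemaError(HdmtxError, ValueError):
    """An input table is missing required columns or has the wrong layout."""


class RowValidationError(HdmtxError, ValueError):
    """One or more rows of an input table failed validation.

    Carries ``errors``: a list of ``(line_number, message)`` tuples.
    """

    def __init__(self, errors):
        self.errors = list(errors)
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in self.errors)
        super().__init__(f"{len(self.errors)} invalid row(s): {lines}")


class ZeroMarginError(HdmtxError, ValueError):
    """A 2x2 table has an empty row or column margin; the odds ratio is undefined."""


class CollinearityError(HdmtxError, ValueError):
    """The regression design matrix is rank deficient."""


class NoEventsError(HdmtxError, ValueError):
    """A survival analysis was requested on data with zero events."""
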