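"""Exception hierarchy for the cdei package.

All errors raised deliberately by the package derive from :class:`CdeiError`
so callers (and the CLI) can distinguish pipeline failures from bugs.
"""


class CdeiError(Exception):
    """Base class for all errors raised by the cdei package."""


class FormatError(CdeiError):
    """An input file violates the expected dialect or an invariant.

    Carries enough location detail (line number, row/column label) to point
    the user at the offending cell.
    """


class UsageError(CdeiError):
    """An operation was called with arguments that violate its contract."""


class PathwaySingularError(CdeiError):
    """(I - B) is numerically singular for a pathway; the linear system
    defining the accuracy vector has no stable solution."""

    def __init__(self, pathway_id: str, message: str | None = None):
        self.pathway_id = pathway_id
        super().__init__(message or f"(I - B) is singular for pathway {pathway_id!r}")


class DegenerateStatisticError(CdeiError):
    """A test statistic is undefined (e.g. one-sample t on a constant vector)."""
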