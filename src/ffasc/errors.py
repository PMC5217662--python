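"""Exception hierarchy for ffasc.

All validation failures raise a named subclass so callers (and the CLI) can
distinguish catalog problems from parse problems from numerical degeneracies.
"""


class FFASCError(Exception):
    """Base class for all ffasc errors."""


class CatalogError(FFASCError):
    """Base class for catalog validation errors."""


class CatalogFormatError(CatalogError):
    """Catalog file does not parse as the documented TSV layout."""


class DuplicateOGError(CatalogError):
    """The same og_id is defined with conflicting category/action."""


class DuplicateMembershipError(CatalogError):
    """A member protein is listed under two different OGs."""


class UnknownCategoryError(CatalogError):
    """Category is not one of nOG / pOG / rOG."""


class UnknownActionError(CatalogError):
    """Action label is not one of the recognised engineering actions."""


class ParseError(FFASCError):
    """A search-output line could not be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class UnknownQueryProteinError(FFASCError):
    """A homology hit references a query protein absent from the catalog."""


class UnknownSpeciesError(FFASCError):
    """A hit references a species id not in the declared species list."""


class MatrixAlignmentError(FFASCError):
    """Matrix columns do not align with the catalog OG order."""


class DegenerateNormalizationError(FFASCError):
    """All scores equal: min-max normalization is undefined."""


class InfeasibleConfigError(FFASCError):
    """Box bounds and sum constraint admit no feasible weight vector."""


class LabelMismatchError(FFASCError):
    """Two annotation matrices do not share the same label sets."""


class ClusteringError(FFASCError):
    """Invalid clustering request (e.g. k > n, or k < 2 for an index)."""
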