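"""Exception hierarchy shared across the package."""


class SymringError(Exception):
    """Base class for all package errors."""


class PDBFormatError(SymringError, ValueError):
    """Raised when a file contains no parseable ATOM/HETATM records."""


class CoordinateOverflowError(SymringError, ValueError):
    """Raised when a coordinate cannot be represented in fixed PDB columns (|x| >= 10000 A)."""


class EmptyInputError(SymringError, ValueError):
    """Raised when an operation that requires at least one element receives none."""


class DegenerateGeometryError(SymringError, ValueError):
    """Raised for rank-deficient point sets (e.g. collinear input to principal axes)."""

    def __init__(self, message: str, rank: int | None = None):
        super().__init__(message)
        self.rank = rank


class CorrespondenceError(SymringError, ValueError):
    """Raised when two coordinate sets that must correspond 1:1 differ in length."""


class ChainCountError(SymringError, ValueError):
    """Raised when a structure has too few (or the wrong number of) chains."""


class TemplateError(SymringError, ValueError):
    """Raised when a dimer template does not have exactly two chains."""


class RingGeometryError(SymringError, RuntimeError):
    """Raised when the ring-radius search cannot bracket the requested neighbour distance."""


class ChainNotFoundError(SymringError, KeyError):
    """Raised when a requested chain id is absent from a structure."""


class ResidueNotFoundError(SymringError, KeyError):
    """Raised when a requested residue is absent from a structure."""


class HalfDecayNotReachedError(SymringError, ValueError):
    """Raised when a progress curve never falls to half of its initial value.

    Carries ``final_fraction``: the last observed value divided by the initial one.
    """

    def __init__(self, message: str, final_fraction: float):
        super().__init__(message)
        self.final_fraction = final_fraction


class KineticsDesignError(SymringError, ValueError):
    """Raised for kinetic datasets that cannot support a fit (e.g. <3 distinct concentrations)."""
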