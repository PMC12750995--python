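"""Exception hierarchy shared across the package."""


class PmkError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PmkError):
    """A structure (SMILES/SDF) could not be parsed."""


class NoE3Match(PmkError):
    """No pattern of the E3 ligand library matches the molecule."""


class AmbiguousMatch(PmkError):
    """Two disjoint E3 patterns match; user override required."""

    def __init__(self, message, matches=None):
        super().__init__(message)
        self.matches = matches or []


class DecompositionError(PmkError):
    """The E3/linker/POI partition could not be delineated."""


class UnknownElement(PmkError):
    """Element symbol missing from the monoisotopic mass table."""


class EmptyInput(PmkError):
    """An operation requiring at least one record received none."""


class EmptySubset(PmkError):
    """Center of mass requested for an empty atom subset."""


class MissingAnchor(PmkError):
    """A required linker anchor atom is undefined."""


class DegenerateGeometry(PmkError):
    """A geometric denominator (e.g. the 2D reference length) is zero."""


class NotApplicable(PmkError):
    """The quantity is undefined for this input (e.g. empty linker)."""


class UnknownRadius(PmkError):
    """No van der Waals radius tabulated for an element."""


class InsufficientRange(PmkError):
    """A profile does not extend into the bulk-water region."""


class OutOfRange(PmkError):
    """Interpolation target grid exceeds the profile's z range."""


class GridMismatch(PmkError):
    """Profiles are not on a common z grid."""


class NotNormalized(PmkError):
    """Barrier extraction requires a bulk-water-referenced profile."""


class InvalidGrid(PmkError):
    """Profile grid parameters are inconsistent."""


class DegenerateInput(PmkError):
    """Regression input has no variance in x."""


class InvalidThresholds(PmkError):
    """Permeability thresholds are not ordered low < high."""


class ZeroVector(PmkError):
    """Orientation angles requested for a zero-length vector."""


class DegenerateDomain(PmkError):
    """A structural domain has no heavy atoms."""


class NegativeConcentration(PmkError):
    """A concentration is negative."""


class ZeroHomogenate(PmkError):
    """Homogenate concentration is zero; binding undefined."""


class InsufficientTimepoints(PmkError):
    """Fewer than two receiver time points."""


class NonPositiveDonor(PmkError):
    """Donor concentration must be positive."""


class MissingVolumes(PmkError):
    """Chamber volumes required for mass balance are absent."""


class ValenceError(PmkError):
    """Fragment assembly produced a chemically invalid molecule."""


class InfeasibleTarget(PmkError):
    """Requested contraction targets cannot be realised geometrically."""


class InvalidTruth(PmkError):
    """Ground-truth parameter outside its valid range."""
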