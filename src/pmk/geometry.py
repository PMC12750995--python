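"""Conformer-ensemble geometry: contraction metrics and surface areas.

Molecule contraction compares a conformer's 3D distance between the E3 and
POI ligand centers of mass to the fully stretched 2D reference length
(d_max,2D = d_E3,2D + d_linker,2D + d_POI,2D); linker contraction does the
same for the anchor-to-anchor distance.  Polar and total surface areas are
computed with a deterministic Shrake-Rupley sphere sampling, with a rolling
water probe (1.4 A) for the solvent-accessible variant and a zero probe for
the van der Waals variant.  Ensemble polarity-shielding summaries normalise
the PSA range to the maximum PSA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdDepictor

from .errors import (
    DegenerateGeometry,
    EmptyInput,
    EmptySubset,
    MissingAnchor,
    NotApplicable,
    UnknownRadius,
)

__all__ = [
    "ConformerEnsemble",
    "ContractionMetrics",
    "SurfaceAreas",
    "ShieldingSummary",
    "VDW_RADII",
    "ATOMIC_MASS",
    "center_of_mass",
    "layout_2d",
    "max_extended_distance_2d",
    "molecule_contraction",
    "linker_contraction",
    "contraction_metrics",
    "sphere_points",
    "shrake_rupley_areas",
    "surface_areas",
    "polar_atom_mask",
    "shielding_summary",
]

# Bondi van der Waals radii (A)
VDW_RADII: Mapping[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
}

# average atomic masses (Da) for mass-weighted centers
ATOMIC_MASS: Mapping[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "Br": 79.904,
    "I": 126.904,
}


@dataclass
class ConformerEnsemble:
    """Shared topology plus per-conformer coordinates and relative energies.

    ``coords`` is a list of (n_atoms, 3) arrays in Angstrom; ``energies`` are
    kJ/mol relative to the ensemble minimum (min exactly 0).  ``domains``
    labels every atom with one of {"e3", "linker", "poi"}; hydrogens carry
    the label of their heavy-atom neighbour.
    """

    elements: list
    masses: np.ndarray
    domains: list
    coords: list
    energies: np.ndarray
    solvent: str = "none"
    bonds: list = field(default_factory=list)  # (i, j) atom-index pairs

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        n = len(self.elements)
        for xyz in self.coords:
            if xyz.shape != (n, 3):
                raise ValueError("conformers must share atom count and ordering")
            if not np.all(np.isfinite(xyz)):
                raise ValueError("non-finite coordinates")
        if len(self.energies) and abs(self.energies.min()) > 1e-9:
            raise ValueError("relative energies must have minimum 0")

    @property
    def n_conformers(self) -> int:
        return len(self.coords)

    def domain_atoms(self, domain: str) -> np.ndarray:
        return np.array([i for i, d in enumerate(self.domains) if d == domain], dtype=int)


@dataclass
class ContractionMetrics:
    d_e3_2d: float
    d_linker_2d: float
    d_poi_2d: float
    d_max_2d: float
    d_e3_to_poi_3d: float
    molecule_contraction: float
    linker_contraction: float | None
    distorted_2d: bool = False  # molecule_contraction above 115%


@dataclass
class SurfaceAreas:
    psa_sasa: float
    tsa_sasa: float
    psa_vdw: float
    tsa_vdw: float

    @property
    def polar_fraction(self) -> float:
        return self.psa_sasa / self.tsa_sasa if self.tsa_sasa > 0 else 0.0


@dataclass
class ShieldingSummary:
    psa_max: float
    psa_min: float
    hidden_area: float
    range_fraction: float  # percent of psa_max
    min_psa_bin: str


def center_of_mass(
    coords: np.ndarray,
    masses: np.ndarray,
    atom_subset: Sequence[int] | None = None,
    elements: Sequence[str] | None = None,
    exclude_hydrogens: bool = False,
) -> np.ndarray:
    """Mass-weighted mean position of a subset of atoms."""
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    idx = np.arange(len(masses)) if atom_subset is None else np.asarray(atom_subset, int)
    if exclude_hydrogens:
        if elements is None:
            raise ValueError("exclude_hydrogens requires element symbols")
        idx = np.array([i for i in idx if elements[i] != "H"], dtype=int)
    if idx.size == 0:
        raise EmptySubset("no atoms left in subset")
    w = masses[idx]
    return (coords[idx] * w[:, None]).sum(axis=0) / w.sum()


# ---------------------------------------------------------------------------
# 2D reference geometry
# ---------------------------------------------------------------------------


def layout_2d(mol: Chem.Mol, mean_bond_length: float = 1.5):
    """Deterministic 2D depiction with explicit hydrogens.

    Coordinates are rescaled so the mean heavy-atom bond length equals
    ``mean_bond_length`` Angstrom, making the 2D reference lengths of the
    contraction ratios unit-consistent with 3D coordinates.  Returns
    ``(mol_with_h, coords (n,3))``.
    """
    mol = Chem.Mol(mol)
    rdDepictor.SetPreferCoordGen(True)
    rdDepictor.Compute2DCoords(mol)
    molh = Chem.AddHs(mol, addCoords=True)
    conf = molh.GetConformer()
    xyz = np.array([list(conf.GetAtomPosition(i)) for i in range(molh.GetNumAtoms())])
    lengths = []
    for b in molh.GetBonds():
        if b.GetBeginAtom().GetSymbol() != "H" and b.GetEndAtom().GetSymbol() != "H":
            lengths.append(
                np.linalg.norm(xyz[b.GetBeginAtomIdx()] - xyz[b.GetEndAtomIdx()])
            )
    if lengths:
        xyz *= mean_bond_length / np.mean(lengths)
    return molh, xyz


def max_extended_distance_2d(
    coords_2d: np.ndarray,
    masses: np.ndarray,
    domains: Sequence[str],
    e3_anchor: int,
    poi_anchor: int,
    elements: Sequence[str] | None = None,
    exclude_hydrogens: bool = False,
):
    """The three 2D segment lengths and their sum d_max,2D.

    Segments: E3 COM -> E3 anchor, anchor -> anchor, POI anchor -> POI COM.
    For an empty linker the middle segment is the depicted anchor bond.
    """
    if e3_anchor is None or poi_anchor is None:
        raise MissingAnchor("both anchors are required")
    coords_2d = np.asarray(coords_2d, dtype=float)
    e3_idx = [i for i, d in enumerate(domains) if d == "e3"]
    poi_idx = [i for i, d in enumerate(domains) if d == "poi"]
    com_e3 = center_of_mass(coords_2d, masses, e3_idx, elements, exclude_hydrogens)
    com_poi = center_of_mass(coords_2d, masses, poi_idx, elements, exclude_hydrogens)
    d_e3 = float(np.linalg.norm(com_e3 - coords_2d[e3_anchor]))
    d_link = float(np.linalg.norm(coords_2d[e3_anchor] - coords_2d[poi_anchor]))
    d_poi = float(np.linalg.norm(coords_2d[poi_anchor] - com_poi))
    return d_e3, d_link, d_poi, d_e3 + d_link + d_poi


def molecule_contraction(
    coords_3d: np.ndarray,
    masses: np.ndarray,
    domains: Sequence[str],
    d_max_2d: float,
    elements: Sequence[str] | None = None,
    exclude_hydrogens: bool = False,
) -> float:
    """100 x (3D E3-COM to POI-COM distance) / d_max,2D."""
    if d_max_2d <= 0:
        raise DegenerateGeometry("d_max_2d must be positive")
    e3_idx = [i for i, d in enumerate(domains) if d == "e3"]
    poi_idx = [i for i, d in enumerate(domains) if d == "poi"]
    com_e3 = center_of_mass(coords_3d, masses, e3_idx, elements, exclude_hydrogens)
    com_poi = center_of_mass(coords_3d, masses, poi_idx, elements, exclude_hydrogens)
    return 100.0 * float(np.linalg.norm(com_e3 - com_poi)) / d_max_2d


def linker_contraction(
    coords_3d: np.ndarray,
    e3_anchor: int,
    poi_anchor: int,
    d_linker_2d: float,
    empty_linker: bool = False,
) -> float:
    """100 x (3D anchor-to-anchor distance) / d_linker,2D.

    Undefined for an empty linker (raises :class:`NotApplicable`).
    """
    if empty_linker:
        raise NotApplicable("linker contraction undefined for an empty linker")
    if d_linker_2d <= 0:
        raise DegenerateGeometry("d_linker_2d must be positive")
    d3 = float(np.linalg.norm(np.asarray(coords_3d)[e3_anchor] - np.asarray(coords_3d)[poi_anchor]))
    return 100.0 * d3 / d_linker_2d


def contraction_metrics(
    ensemble: ConformerEnsemble,
    conformer: int,
    coords_2d: np.ndarray,
    e3_anchor: int,
    poi_anchor: int,
    empty_linker: bool = False,
    exclude_hydrogens: bool = False,
) -> ContractionMetrics:
    """All contraction quantities for one conformer of an ensemble."""
    d_e3, d_link, d_poi, d_max = max_extended_distance_2d(
        coords_2d,
        ensemble.masses,
        ensemble.domains,
        e3_anchor,
        poi_anchor,
        ensemble.elements,
        exclude_hydrogens,
    )
    xyz = ensemble.coords[conformer]
    mc = molecule_contraction(
        xyz, ensemble.masses, ensemble.domains, d_max, ensemble.elements, exclude_hydrogens
    )
    if empty_linker:
        lc = None
    else:
        lc = linker_contraction(xyz, e3_anchor, poi_anchor, d_link)
    e3_idx = ensemble.domain_atoms("e3")
    poi_idx = ensemble.domain_atoms("poi")
    com_e3 = center_of_mass(xyz, ensemble.masses, e3_idx, ensemble.elements, exclude_hydrogens)
    com_poi = center_of_mass(xyz, ensemble.masses, poi_idx, ensemble.elements, exclude_hydrogens)
    return ContractionMetrics(
        d_e3_2d=d_e3,
        d_linker_2d=d_link,
        d_poi_2d=d_poi,
        d_max_2d=d_max,
        d_e3_to_poi_3d=float(np.linalg.norm(com_e3 - com_poi)),
        molecule_contraction=mc,
        linker_contraction=lc,
        distorted_2d=mc > 115.0,
    )


# ---------------------------------------------------------------------------
# Surface areas (Shrake-Rupley)
# ---------------------------------------------------------------------------


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-spiral lattice)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def shrake_rupley_areas(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom exposed area of the probe-inflated spheres (A^2)."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float) + probe_radius
    unit = sphere_points(n_points)
    n = len(radii)
    areas = np.zeros(n)
    for i in range(n):
        pts = coords[i] + radii[i] * unit
        exposed = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 > radii[j] ** 2
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * exposed.mean()
    return areas


def polar_atom_mask(
    elements: Sequence[str],
    bonds: Sequence,
    polar_elements: Sequence[str] = ("N", "O"),
) -> np.ndarray:
    """Polar atoms: N, O (configurable) plus hydrogens bonded to them."""
    polar = np.array([e in polar_elements for e in elements], dtype=bool)
    for i, j in bonds:
        if elements[i] == "H" and polar[j]:
            polar[i] = True
        if elements[j] == "H" and polar[i]:
            polar[j] = True
    return polar


def surface_areas(
    coords: np.ndarray,
    elements: Sequence[str],
    bonds: Sequence = (),
    probe_radius: float = 1.4,
    polar_elements: Sequence[str] = ("N", "O"),
    n_points: int = 960,
    radii: Mapping[str, float] | None = None,
) -> SurfaceAreas:
    """Polar and total surface areas, rolling-probe and van der Waals.

    PSA is the area contributed by polar atoms (N, O and hydrogens bonded to
    them by default; sulfur excluded unless listed in ``polar_elements``).
    """
    table = VDW_RADII if radii is None else radii
    try:
        r = np.array([table[e] for e in elements], dtype=float)
    except KeyError as exc:
        raise UnknownRadius(f"no van der Waals radius for {exc.args[0]!r}") from None
    polar = polar_atom_mask(elements, bonds, polar_elements)
    sasa = shrake_rupley_areas(coords, r, probe_radius, n_points)
    vdw = shrake_rupley_areas(coords, r, 0.0, n_points)
    return SurfaceAreas(
        psa_sasa=float(sasa[polar].sum()),
        tsa_sasa=float(sasa.sum()),
        psa_vdw=float(vdw[polar].sum()),
        tsa_vdw=float(vdw.sum()),
    )


def shielding_summary(psa_values: Sequence[float]) -> ShieldingSummary:
    """Ensemble PSA range normalised to the maximum PSA.

    ``hidden_area`` is the shieldable polar surface (max - min over the
    conformers); ``range_fraction`` expresses it as a percent of the maximum.
    The minimum-PSA bin uses 100/150/200 A^2 thresholds.
    """
    vals = np.asarray(list(psa_values), dtype=float)
    if vals.size == 0:
        raise EmptyInput("at least one PSA value required")
    psa_max = float(vals.max())
    psa_min = float(vals.min())
    hidden = psa_max - psa_min
    frac = 100.0 * hidden / psa_max if psa_max > 0 else 0.0
    if psa_min < 100:
        bin_ = "<100"
    elif psa_min < 150:
        bin_ = "100-150"
    elif psa_min < 200:
        bin_ = "150-200"
    else:
        bin_ = ">200"
    return ShieldingSummary(psa_max, psa_min, hidden, frac, bin_)
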