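"""Tripartite PROTAC chemistry: decomposition, 2D descriptors, linker motifs.

A PROTAC (proteolysis-targeting chimera) joins an E3-ligase ligand and a
protein-of-interest (POI) ligand through a linker.  This module parses
structures, splits them into the three domains against a library of E3-core
substructure patterns, computes standard 2D descriptors on the whole molecule
and on each hydrogen-capped domain, classifies linker motifs (alkyl runs, PEG
repeats, amides, rings), and validates elemental formulas by the monoisotopic
[M+H]+ mass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .errors import (
    AmbiguousMatch,
    DecompositionError,
    EmptyInput,
    NoE3Match,
    ParseError,
    UnknownElement,
)

__all__ = [
    "E3Class",
    "LinkerClass",
    "ProtacRecord",
    "Decomposition",
    "DescriptorSet",
    "LinkerMotifProfile",
    "E3Pattern",
    "default_e3_library",
    "load_e3_library",
    "decompose",
    "compute_2d_descriptors",
    "monoisotopic_mass",
    "monoisotopic_mh",
    "classify_linker_motifs",
    "assign_linker_class",
    "summarize_dataset",
    "mw_cap_correction",
    "tpsa_cap_correction",
]


class E3Class(str, Enum):
    CRBN = "CRBN"
    VHL = "VHL"
    IAP = "IAP"
    OTHER = "OTHER"
    UNKNOWN = "UNKNOWN"


class LinkerClass(str, Enum):
    RINGS_ONLY = "RINGS_ONLY"
    PEG_LONG = "PEG_LONG"
    PEG_SHORT = "PEG_SHORT"
    ALKYL = "ALKYL"
    RINGS_PLUS_SHORT_CHAINS = "RINGS_PLUS_SHORT_CHAINS"
    EMPTY = "EMPTY"
    OTHER = "OTHER"


@dataclass
class ProtacRecord:
    """One compound: identifier, structure, E3-class annotation."""

    id: str
    smiles: str
    e3_class: E3Class = E3Class.UNKNOWN
    annotations: dict = field(default_factory=dict)


@dataclass
class Decomposition:
    """The three domains with anchor atoms and per-atom labels.

    ``atom_domains`` holds one of ``{"e3", "linker", "poi"}`` per heavy atom
    of the parent molecule, indexed by RDKit atom index.  ``e3_anchor`` is the
    E3-side atom that carries the (first) cut bond; ``poi_anchor`` the
    POI-side one.  For an empty linker the two anchors are directly bonded.
    """

    e3_smiles: str
    linker_smiles: str
    poi_smiles: str
    e3_anchor: int
    poi_anchor: int
    atom_domains: list
    e3_class: E3Class = E3Class.UNKNOWN
    pattern_name: str = ""

    @property
    def has_linker(self) -> bool:
        return self.linker_smiles != ""

    def domain_atoms(self, domain: str) -> list:
        return [i for i, d in enumerate(self.atom_domains) if d == domain]


@dataclass
class DescriptorSet:
    mw: float
    clogp: float
    tpsa: float
    hbd: int
    hba: int
    nrotb: int

    def as_dict(self) -> dict:
        return {
            "mw": self.mw,
            "clogp": self.clogp,
            "tpsa": self.tpsa,
            "hbd": self.hbd,
            "hba": self.hba,
            "nrotb": self.nrotb,
        }


@dataclass
class LinkerMotifProfile:
    alkyl_max_run: int = 0
    peg_monomers: int = 0
    has_amide: bool = False
    ring_count: int = 0
    ring_types: tuple = ()
    has_azo: bool = False
    has_alkyne: bool = False
    has_sulfur: bool = False
    # not part of the minimal field list, but needed to decide RINGS_ONLY
    ring_atom_count: int = 0


@dataclass
class E3Pattern:
    """A named SMARTS with an optional atom-map-1 exit-vector marker."""

    name: str
    e3_class: E3Class
    smarts: str

    def query(self) -> Chem.Mol:
        q = Chem.MolFromSmarts(self.smarts)
        if q is None:
            raise ParseError(f"invalid SMARTS for pattern {self.name!r}")
        return q


# ---------------------------------------------------------------------------
# E3 pattern library
# ---------------------------------------------------------------------------

# Shipped defaults: glutarimide-phthalimide / isoindolinone CRBN cores
# (thalidomide / pomalidomide / lenalidomide-type, N- and O-linked) and the
# hydroxyproline / tert-leucine / methylthiazolyl-benzyl VHL core.  The exit
# vector is the atom carrying map number 1.  Users may extend via YAML.
_DEFAULT_LIBRARY = [
    E3Pattern(
        "crbn_pomalidomide_n",
        E3Class.CRBN,
        "O=C1CCC(N2C(=O)c3cccc([NX3:1])c3C2=O)C(=O)N1",
    ),
    E3Pattern(
        "crbn_thalidomide_o",
        E3Class.CRBN,
        "O=C1CCC(N2C(=O)c3cccc([OX2:1])c3C2=O)C(=O)N1",
    ),
    E3Pattern(
        "crbn_lenalidomide_n",
        E3Class.CRBN,
        "O=C1CCC(N2Cc3cccc([NX3:1])c3C2=O)C(=O)N1",
    ),
    E3Pattern(
        "vhl_vh032_amine",
        E3Class.VHL,
        "CC(C)(C)C([NX3:1])C(=O)N1CC(O)CC1C(=O)NCc1ccc(-c2scnc2C)cc1",
    ),
]


def default_e3_library() -> list:
    return list(_DEFAULT_LIBRARY)


def load_e3_library(path) -> list:
    """Load an E3 pattern library from YAML.

    Schema: a list of ``{name, e3_class, smarts}`` mappings; the exit vector
    is the SMARTS atom with map number 1.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = []
    for entry in raw:
        out.append(
            E3Pattern(
                name=str(entry["name"]),
                e3_class=E3Class(entry["e3_class"]),
                smarts=str(entry["smarts"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Parsing helpers
# ---------------------------------------------------------------------------


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def _require_connected(mol: Chem.Mol) -> None:
    if len(Chem.GetMolFrags(mol)) != 1:
        raise ParseError("structure must be a single connected molecule")


def _fragment_smiles(mol: Chem.Mol, atoms: Sequence[int]) -> str:
    """Canonical SMILES of an induced subgraph, hydrogen-capped.

    Every bond cut by the extraction is replaced by an explicit hydrogen on
    the fragment side, so aromatic nitrogens keep a kekulizable valence.
    """
    atoms = set(atoms)
    if not atoms:
        return ""
    rw = Chem.RWMol(mol)
    for idx in atoms:
        atom = rw.GetAtomWithIdx(idx)
        cuts = sum(1 for nb in atom.GetNeighbors() if nb.GetIdx() not in atoms)
        if cuts:
            atom.SetNumExplicitHs(atom.GetTotalNumHs() + cuts)
            atom.SetNoImplicit(True)
    for idx in sorted(set(range(mol.GetNumAtoms())) - atoms, reverse=True):
        rw.RemoveAtom(idx)
    frag = rw.GetMol()
    try:
        Chem.SanitizeMol(frag)
    except Exception as exc:  # pragma: no cover - defensive
        raise DecompositionError(f"fragment capping failed: {exc}") from exc
    return Chem.MolToSmiles(frag)


# ---------------------------------------------------------------------------
# Decomposition
# ---------------------------------------------------------------------------


def _ring_systems(mol: Chem.Mol, allowed: set) -> list:
    """Fused ring systems restricted to atoms in ``allowed``."""
    systems: list = []
    for ring in mol.GetRingInfo().AtomRings():
        ring = set(ring)
        if not ring <= allowed:
            continue
        merged = ring
        keep = []
        for sys_ in systems:
            if sys_ & merged:
                merged |= sys_
            else:
                keep.append(sys_)
        keep.append(merged)
        systems = keep
    return systems


def _resolve_matches(mol: Chem.Mol, pattern: E3Pattern) -> list:
    """All usable matches as (match_atoms, anchor, exit_atom) triples.

    A usable match touches the rest of the molecule through exactly one bond,
    at the exit-vector atom if the pattern marks one.
    """
    query = pattern.query()
    mapped = None
    for atom in query.GetAtoms():
        if atom.GetAtomMapNum() == 1:
            mapped = atom.GetIdx()
    out = []
    for match in mol.GetSubstructMatches(query, useChirality=False, uniquify=True):
        mset = frozenset(match)
        if any(mset == prev[0] for prev in out):
            continue
        external = []  # (core atom, outside neighbour)
        for idx in match:
            for nb in mol.GetAtomWithIdx(idx).GetNeighbors():
                if nb.GetIdx() not in mset:
                    external.append((idx, nb.GetIdx()))
        if len(external) != 1:
            continue
        anchor, exit_atom = external[0]
        if mapped is not None and match[mapped] != anchor:
            continue
        out.append((mset, anchor, exit_atom))
    return out


def decompose(
    molecule,
    e3_library: Sequence[E3Pattern] | None = None,
) -> Decomposition:
    """Split a PROTAC into E3 ligand, linker and POI ligand domains.

    The E3 domain is the library pattern match; the POI ligand is the fused
    ring system topologically farthest from the E3 exit vector together with
    everything attached beyond it; the linker is the remainder.  Fragments
    are hydrogen-capped at the two cut bonds.

    Raises :class:`NoE3Match` when no pattern matches and
    :class:`AmbiguousMatch` when two atom-disjoint patterns match.
    """
    if isinstance(molecule, str):
        molecule = mol_from_smiles(molecule)
    _require_connected(molecule)
    library = list(e3_library) if e3_library is not None else default_e3_library()

    hits = []
    for pattern in library:
        for res in _resolve_matches(molecule, pattern):
            hits.append((pattern, *res))
    if not hits:
        raise NoE3Match("no E3 ligand pattern matches the molecule")
    # disjoint hits from different patterns are genuinely ambiguous
    for i in range(len(hits)):
        for j in range(i + 1, len(hits)):
            if not (hits[i][1] & hits[j][1]):
                raise AmbiguousMatch(
                    f"disjoint E3 matches: {hits[i][0].name} and {hits[j][0].name}",
                    matches=[hits[i][0].name, hits[j][0].name],
                )
    # overlapping hits: keep the largest core (most specific)
    pattern, e3_atoms, e3_anchor, exit_atom = max(hits, key=lambda h: len(h[1]))

    n_atoms = molecule.GetNumAtoms()
    rest = set(range(n_atoms)) - e3_atoms
    if not rest:
        raise DecompositionError("molecule is only an E3 core; no POI ligand")

    systems = _ring_systems(molecule, rest)
    if not systems:
        raise DecompositionError(
            "cannot delineate a POI ligand: no ring system outside the E3 core"
        )
    dmat = Chem.GetDistanceMatrix(molecule)
    far = max(systems, key=lambda s: (min(dmat[exit_atom][a] for a in s), sorted(s)))

    if exit_atom in far:
        poi_atoms = set(rest)
    else:
        # POI = farthest ring system + components of rest\far not holding exit
        blocked = far
        seen = {exit_atom}
        stack = [exit_atom]
        while stack:
            cur = stack.pop()
            for nb in molecule.GetAtomWithIdx(cur).GetNeighbors():
                k = nb.GetIdx()
                if k in rest and k not in blocked and k not in seen:
                    seen.add(k)
                    stack.append(k)
        poi_atoms = (rest - seen) | far
    linker_atoms = rest - poi_atoms

    if linker_atoms:
        boundary = set()
        for a in poi_atoms:
            for nb in molecule.GetAtomWithIdx(a).GetNeighbors():
                if nb.GetIdx() in linker_atoms:
                    boundary.add(a)
        if len(boundary) != 1:
            raise DecompositionError(
                "POI ligand attaches to the linker through more than one bond"
            )
        poi_anchor = boundary.pop()
    else:
        poi_anchor = exit_atom

    domains = ["poi"] * n_atoms
    for a in e3_atoms:
        domains[a] = "e3"
    for a in linker_atoms:
        domains[a] = "linker"

    return Decomposition(
        e3_smiles=_fragment_smiles(molecule, sorted(e3_atoms)),
        linker_smiles=_fragment_smiles(molecule, sorted(linker_atoms)),
        poi_smiles=_fragment_smiles(molecule, sorted(poi_atoms)),
        e3_anchor=e3_anchor,
        poi_anchor=poi_anchor,
        atom_domains=domains,
        e3_class=pattern.e3_class,
        pattern_name=pattern.name,
    )


# ---------------------------------------------------------------------------
# 2D descriptors
# ---------------------------------------------------------------------------


def compute_2d_descriptors(molecule) -> DescriptorSet:
    """MW, atom-contribution cLogP, TPSA, Lipinski HBD/HBA, rotatable bonds.

    Computed on the unprotonated (input) form; hydrogen-bond counts are the
    Lipinski N/O conventions (N-H and O-H donors; N and O acceptors).
    """
    if isinstance(molecule, str):
        if molecule == "":
            return DescriptorSet(0.0, 0.0, 0.0, 0, 0, 0)
        molecule = mol_from_smiles(molecule)
    return DescriptorSet(
        mw=Descriptors.MolWt(molecule),
        clogp=Crippen.MolLogP(molecule),
        tpsa=rdMolDescriptors.CalcTPSA(molecule),
        hbd=Lipinski.NHOHCount(molecule),
        hba=Lipinski.NOCount(molecule),
        nrotb=Lipinski.NumRotatableBonds(molecule),
    )


# Monoisotopic masses of the most abundant isotope (Da), CODATA/IUPAC values.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "H": 1.0078250319,
    "D": 2.0141017780,
    "B": 11.0093055,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "F": 18.9984031627,
    "Na": 22.9897692820,
    "Si": 27.9769265347,
    "P": 30.9737615120,
    "S": 31.9720706912,
    "Cl": 34.9688527100,
    "K": 38.9637064864,
    "Br": 78.9183376,
    "I": 126.9044719,
}

PROTON_MASS = 1.00727646677  # H atom minus the electron (Da)

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict:
    """Parse a Hill-style elemental formula into {element: count}."""
    counts: dict = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise UnknownElement(f"malformed formula at {formula[pos:]!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise UnknownElement(f"malformed formula at {formula[pos:]!r}")
    return counts


def monoisotopic_mass(formula) -> float:
    """Monoisotopic mass of the neutral composition (Da)."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    total = 0.0
    for element, count in formula.items():
        try:
            total += MONOISOTOPIC_MASS[element] * count
        except KeyError:
            raise UnknownElement(f"no monoisotopic mass for {element!r}") from None
    return total


def monoisotopic_mh(formula) -> float:
    """Monoisotopic [M+H]+ mass (Da): neutral mass plus one proton.

    An empty formula returns the bare-proton mass 1.00728.
    """
    return monoisotopic_mass(formula) + PROTON_MASS


# ---------------------------------------------------------------------------
# Linker motifs
# ---------------------------------------------------------------------------

_AMIDE = Chem.MolFromSmarts("[CX3](=O)[NX3]")
_AZO = Chem.MolFromSmarts("[NX2]=[NX2]")
_ALKYNE = Chem.MolFromSmarts("C#C")


def _is_chain_carbon(atom: Chem.Atom) -> bool:
    """An sp3 CH2-type chain unit.

    Hydrogen-capped fragments turn the attachment CH2 into CH3, so carbons
    with 2-3 hydrogens and at most two heavy neighbours count as chain units.
    """
    return (
        atom.GetSymbol() == "C"
        and not atom.GetIsAromatic()
        and not atom.IsInRing()
        and atom.GetHybridization() == Chem.HybridizationType.SP3
        and 2 <= atom.GetTotalNumHs() <= 3
        and atom.GetDegree() <= 2
    )


def _is_chain_ether_oxygen(atom: Chem.Atom) -> bool:
    return (
        atom.GetSymbol() == "O"
        and not atom.IsInRing()
        and atom.GetDegree() <= 2
        and atom.GetTotalNumHs() <= 1
    )


def _longest_path(adjacency: Mapping[int, list], nodes: set) -> int:
    """Longest simple path (node count) in a small subgraph."""
    best = 0

    def walk(cur: int, visited: set) -> None:
        nonlocal best
        best = max(best, len(visited))
        for nb in adjacency[cur]:
            if nb in nodes and nb not in visited:
                visited.add(nb)
                walk(nb, visited)
                visited.remove(nb)

    for start in nodes:
        walk(start, {start})
    return best


def _max_disjoint(matches: list) -> int:
    """Maximum number of pairwise atom-disjoint matches (exact, small n)."""
    matches = [frozenset(m) for m in matches]

    def solve(remaining: tuple) -> int:
        if not remaining:
            return 0
        head, *tail = remaining
        skip = solve(tuple(tail))
        take = 1 + solve(tuple(m for m in tail if not (m & head)))
        return max(skip, take)

    return solve(tuple(sorted(matches, key=sorted)))


def classify_linker_motifs(linker_smiles: str) -> LinkerMotifProfile:
    """Count alkyl runs, PEG repeats, amides, rings and flag motifs.

    An empty linker gives the all-zero profile.  Counting is performed on the
    molecular graph, so it is invariant to SMILES atom ordering.
    """
    if linker_smiles == "":
        return LinkerMotifProfile()
    mol = mol_from_smiles(linker_smiles)

    adjacency = {
        a.GetIdx(): [nb.GetIdx() for nb in a.GetNeighbors()] for a in mol.GetAtoms()
    }
    chain_c = {a.GetIdx() for a in mol.GetAtoms() if _is_chain_carbon(a)}
    # an alkyl run must not pass through ether oxygens
    alkyl_max_run = _longest_path(adjacency, chain_c) if chain_c else 0

    # PEG: O-CH2-CH2 triples, maximum pairwise-disjoint set
    triples = []
    for o in (a for a in mol.GetAtoms() if _is_chain_ether_oxygen(a)):
        for c1 in o.GetNeighbors():
            if c1.GetIdx() not in chain_c:
                continue
            for c2 in c1.GetNeighbors():
                if c2.GetIdx() == o.GetIdx() or c2.GetIdx() not in chain_c:
                    continue
                triples.append({o.GetIdx(), c1.GetIdx(), c2.GetIdx()})
    peg = _max_disjoint(triples) if triples else 0

    rings = mol.GetRingInfo().AtomRings()
    ring_types = []
    for ring in rings:
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        symbols = sorted(a.GetSymbol() for a in atoms)
        aromatic = all(a.GetIsAromatic() for a in atoms)
        if (
            len(ring) == 6
            and symbols == ["C", "C", "C", "C", "N", "N"]
            and not aromatic
        ):
            ring_types.append("piperazine")
        elif len(ring) == 5 and aromatic and symbols.count("N") == 3:
            ring_types.append("triazole")
        else:
            ring_types.append("other")

    return LinkerMotifProfile(
        alkyl_max_run=alkyl_max_run,
        peg_monomers=peg,
        has_amide=mol.HasSubstructMatch(_AMIDE),
        ring_count=len(rings),
        ring_types=tuple(sorted(ring_types)),
        has_azo=mol.HasSubstructMatch(_AZO),
        has_alkyne=mol.HasSubstructMatch(_ALKYNE),
        has_sulfur=any(a.GetSymbol() == "S" for a in mol.GetAtoms()),
        ring_atom_count=len({i for ring in rings for i in ring}),
    )


def assign_linker_class(profile: LinkerMotifProfile, heavy_atom_count: int) -> LinkerClass:
    """Deterministic linker group, precedence
    EMPTY > RINGS_ONLY > PEG_LONG > PEG_SHORT > ALKYL > RINGS_PLUS_SHORT_CHAINS > OTHER.

    PEG_LONG means >=3 -(OCH2CH2)- monomers (>=9 chain atoms), with or
    without rings; ALKYL requires a run of >=3 CH2 units and no PEG.
    """
    if heavy_atom_count == 0:
        return LinkerClass.EMPTY
    if profile.ring_count > 0 and profile.ring_atom_count == heavy_atom_count:
        return LinkerClass.RINGS_ONLY
    if profile.peg_monomers >= 3:
        return LinkerClass.PEG_LONG
    if profile.peg_monomers >= 1:
        return LinkerClass.PEG_SHORT
    if profile.alkyl_max_run >= 3:
        return LinkerClass.ALKYL
    if profile.ring_count > 0:
        return LinkerClass.RINGS_PLUS_SHORT_CHAINS
    return LinkerClass.OTHER


# ---------------------------------------------------------------------------
# Cap corrections for additivity checks
# ---------------------------------------------------------------------------

_H_AVG = 1.008  # average H mass used by Descriptors.MolWt


def mw_cap_correction(decomposition: Decomposition) -> float:
    """Total cap mass added by hydrogen-capping the cut bonds.

    Each cut bond adds one hydrogen to each side; parent MW equals the sum of
    the three fragment MWs minus this correction.
    """
    n_cuts = 2 if decomposition.has_linker else 1
    return 2.0 * n_cuts * _H_AVG


def tpsa_cap_correction(parent: Chem.Mol, decomposition: Decomposition) -> float:
    """TPSA excess of the capped fragments over the parent molecule.

    TPSA is a sum of per-atom fragment contributions that depend only on an
    atom's local environment, so capping perturbs the contribution of anchor
    atoms (and their cut-bond partners) only.  The correction is the summed
    contribution difference at those atoms between fragment and parent.
    """
    parent_contribs = rdMolDescriptors._CalcTPSAContribs(parent)
    total = 0.0
    for domain in ("e3", "linker", "poi"):
        atoms = decomposition.domain_atoms(domain)
        if not atoms:
            continue
        smi = Chem.MolFragmentToSmiles(parent, atomsToUse=atoms, canonical=False)
        order_s = parent.GetProp("_smilesAtomOutputOrder") if parent.HasProp(
            "_smilesAtomOutputOrder"
        ) else None
        # map fragment atoms back to parent indices via the output order
        order = [int(x) for x in order_s.strip("[]").split(",") if x] if order_s else atoms
        frag = Chem.MolFromSmiles(smi)
        frag_contribs = rdMolDescriptors._CalcTPSAContribs(frag)
        for frag_idx, parent_idx in enumerate(order):
            total += frag_contribs[frag_idx] - parent_contribs[parent_idx]
    return total


# ---------------------------------------------------------------------------
# Dataset summary
# ---------------------------------------------------------------------------


def _stereo_free(smiles: str) -> str:
    if smiles == "":
        return ""
    mol = mol_from_smiles(smiles)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def summarize_dataset(records: Iterable) -> pd.DataFrame:
    """Per-E3-class descriptor table: median and (min-max) range.

    ``records`` yields ``(ProtacRecord, Decomposition)`` pairs.  Rows cover
    the full molecule and the three domains for each descriptor; a companion
    row block counts unique E3 ligands / linkers / POI ligands with
    stereochemistry stripped.
    """
    rows = []
    uniques: dict = {}
    for record, dec in records:
        parts = {
            "full": record.smiles,
            "e3_ligand": dec.e3_smiles,
            "linker": dec.linker_smiles,
            "poi_ligand": dec.poi_smiles,
        }
        cls = dec.e3_class.value
        bucket = uniques.setdefault(cls, {"e3_ligand": set(), "linker": set(), "poi_ligand": set()})
        for part in ("e3_ligand", "linker", "poi_ligand"):
            bucket[part].add(_stereo_free(parts[part]))
        for part, smi in parts.items():
            desc = compute_2d_descriptors(smi)
            for name, value in desc.as_dict().items():
                rows.append(
                    {"e3_class": cls, "part": part, "descriptor": name, "value": value}
                )
    if not rows:
        raise EmptyInput("no records to summarize")
    df = pd.DataFrame(rows)
    summary = (
        df.groupby(["e3_class", "part", "descriptor"])["value"]
        .agg(median="median", min="min", max="max", n="count")
        .reset_index()
    )
    unique_rows = [
        {"e3_class": cls, "part": part, "descriptor": "n_unique", "median": np.nan,
         "min": np.nan, "max": np.nan, "n": len(vals)}
        for cls, parts in uniques.items()
        for part, vals in parts.items()
    ]
    return pd.concat([summary, pd.DataFrame(unique_rows)], ignore_index=True)
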