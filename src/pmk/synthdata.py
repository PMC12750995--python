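"""Synthetic inputs with known ground truth.

Everything the analysis modules consume can be generated here: PROTACs
assembled from E3-core / linker / POI fragment libraries (the inverse of
decomposition), conformer ensembles built geometrically to hit prescribed
molecule/linker contraction values exactly, parametric membrane free-energy
profiles (two interface Gaussian wells plus a core Gaussian barrier, plus
noise), orientation states drawn from a prescribed group distribution, and
dialysis/transport assay data forward-simulated from a known fu or Papp.

Ensembles are geometric constructions, not force-field samples: the analysis
operations consume coordinates and energies, so exact, prescribable geometry
is worth more than physical realism.  All generators are pure functions of
(parameters, seed); the counter-based Philox generator keeps streams
reproducible across platforms.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from scipy.optimize import brentq

from . import geometry
from .assays import DialysisMeasurement, TransportExperiment
from .chemistry import Decomposition, E3Class, ProtacRecord, mol_from_smiles
from .errors import InfeasibleTarget, InvalidGrid, InvalidTruth, ValenceError
from .geometry import ATOMIC_MASS, ConformerEnsemble
from .profiles import FreeEnergyProfile, ProfileGrid

__all__ = [
    "GroundTruth",
    "ProfileArchetype",
    "fragment_libraries",
    "assemble_protac",
    "generate_conformer_ensemble",
    "generate_profiles",
    "generate_orientation_states",
    "generate_dialysis_data",
    "generate_transport_data",
    "simulate_transport",
    "generate_cohort",
    "ARCHETYPE_INTERFACE_BINDER",
    "ARCHETYPE_CORE_BLOCKED",
]


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(seed))


@dataclass
class GroundTruth:
    """True values serialized alongside every generated dataset."""

    seed: int
    params: dict = field(default_factory=dict)
    values: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            return str(o)

        return json.dumps(asdict(self), default=default, indent=2)


# ---------------------------------------------------------------------------
# Fragment libraries and assembly
# ---------------------------------------------------------------------------

# E3 cores attach through [*:1]; linkers bridge [*:1] (E3 side) to [*:2]
# (POI side); POI ligands attach through a ring atom at [*:2].
E3_CORES = {
    "crbn_pomalidomide_n": ("CRBN", "O=C1CCC(N2C(=O)c3cccc(N[*:1])c3C2=O)C(=O)N1"),
    "crbn_thalidomide_o": ("CRBN", "O=C1CCC(N2C(=O)c3cccc(O[*:1])c3C2=O)C(=O)N1"),
    "crbn_lenalidomide_n": ("CRBN", "O=C1CCC(N2Cc3cccc(N[*:1])c3C2=O)C(=O)N1"),
    "vhl_vh032": (
        "VHL",
        "CC(C)(C)C(N[*:1])C(=O)N1CC(O)CC1C(=O)NCc1ccc(-c2scnc2C)cc1",
    ),
}

POI_LIGANDS = {
    "poi_cresol": "[*:2]c1ccc(O)c(C)c1",
    "poi_toluene": "[*:2]c1ccc(C)cc1",
    "poi_naphthalene": "[*:2]c1ccc2ccccc2c1",
    "poi_trifluorotoluene": "[*:2]c1ccc(C(F)(F)F)cc1",
}


def alkyl_linker(n: int) -> str:
    """Saturated -(CH2)n- chain linker."""
    return "[*:1]" + "C" * n + "[*:2]" if n > 0 else ""


def peg_linker(n: int) -> str:
    """-(CH2CH2O)n- polyethylene glycol linker (3 chain atoms per monomer)."""
    return "[*:1]" + "CCO" * n + "[*:2]" if n > 0 else ""


NAMED_LINKERS = {
    "linker_piperazine_ring": "[*:1]N1CCN(CC1)[*:2]",
    "linker_triazole_ring": "[*:1]c1cn([*:2])nn1",
    "linker_piperazine_chains": "[*:1]CCN1CCN(CC1)CC[*:2]",
    "linker_amide_peg": "[*:1]CC(=O)NCCOCCO[*:2]",
    "linker_empty": "",
}


def fragment_libraries() -> dict:
    """Named SMILES libraries: E3 cores, linkers, POI ligands.

    Linkers include parametric alkyl(n)/peg(n) examples alongside ring-based
    motifs; attachment points carry atom maps for assembly.
    """
    linkers = dict(NAMED_LINKERS)
    for n in (3, 4, 5, 6, 8):
        linkers[f"linker_alkyl{n}"] = alkyl_linker(n)
    for n in (1, 2, 3, 4):
        linkers[f"linker_peg{n}"] = peg_linker(n)
    return {
        "e3_ligands": {k: v[1] for k, v in E3_CORES.items()},
        "e3_classes": {k: v[0] for k, v in E3_CORES.items()},
        "linkers": linkers,
        "poi_ligands": dict(POI_LIGANDS),
    }


def _cap_with_h(smiles_with_dummy: str) -> str:
    """Canonical SMILES with attachment dummies replaced by hydrogen."""
    if smiles_with_dummy == "":
        return ""
    mol = Chem.RWMol(mol_from_smiles(smiles_with_dummy))
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomicNum(1)
            atom.SetAtomMapNum(0)
    out = Chem.RemoveHs(mol.GetMol())
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def assemble_protac(
    e3_smiles: str,
    linker_smiles: str,
    poi_smiles: str,
    record_id: str = "synthetic",
    e3_class: str = "UNKNOWN",
) -> tuple:
    """Join fragments at their attachment maps; inverse of decomposition.

    An empty linker bonds the E3 exit vector directly to the POI attachment.
    Returns ``(ProtacRecord, GroundTruth)`` where the truth holds the three
    hydrogen-capped fragment SMILES.
    """
    e3 = mol_from_smiles(e3_smiles)
    poi = mol_from_smiles(poi_smiles)
    if linker_smiles == "":
        poi = Chem.RWMol(poi)
        for atom in poi.GetAtoms():
            if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum() == 2:
                atom.SetAtomMapNum(1)
        combined = Chem.CombineMols(e3, poi.GetMol())
    else:
        linker = mol_from_smiles(linker_smiles)
        combined = Chem.CombineMols(Chem.CombineMols(e3, linker), poi)
    try:
        zipped = Chem.molzip(combined)
        Chem.SanitizeMol(zipped)
    except Exception as exc:
        raise ValenceError(f"assembly failed: {exc}") from exc
    smiles = Chem.MolToSmiles(zipped)
    record = ProtacRecord(id=record_id, smiles=smiles, e3_class=E3Class(e3_class))
    truth = GroundTruth(
        seed=0,
        params={
            "e3_smiles": e3_smiles,
            "linker_smiles": linker_smiles,
            "poi_smiles": poi_smiles,
        },
        values={
            "e3_capped": _cap_with_h(e3_smiles),
            "linker_capped": _cap_with_h(linker_smiles),
            "poi_capped": _cap_with_h(poi_smiles),
            "e3_class": e3_class,
        },
    )
    return record, truth


# ---------------------------------------------------------------------------
# Conformer ensembles with prescribed contraction
# ---------------------------------------------------------------------------


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a to unit vector b (Rodrigues)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        v = np.cross(a, perp)
        v /= np.linalg.norm(v)
        return 2.0 * np.outer(v, v) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    vx = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * vx + (1 - np.cos(angle)) * (vx @ vx)


def _truncated_exponential(rng, n, mean=5.0, upper=21.0):
    u = rng.uniform(size=n)
    return -mean * np.log1p(-u * (1.0 - np.exp(-upper / mean)))


def contraction_bounds(record: ProtacRecord, decomposition: Decomposition, link_pct: float):
    """Feasible molecule-contraction range (percent) at a given linker target.

    The hinged-rigid-body construction can realise COM distances between
    |L - d_E3 - d_POI| and L + d_E3 + d_POI, with L the target anchor
    separation.
    """
    mol = mol_from_smiles(record.smiles)
    molh, xy = geometry.layout_2d(mol)
    elements = [a.GetSymbol() for a in molh.GetAtoms()]
    masses = np.array([ATOMIC_MASS[e] for e in elements])
    domains = list(decomposition.atom_domains)
    for atom in molh.GetAtoms():
        if atom.GetIdx() >= mol.GetNumAtoms():
            domains.append(domains[atom.GetNeighbors()[0].GetIdx()])
    d_e3, d_link, d_poi, d_max = geometry.max_extended_distance_2d(
        xy, masses, domains, decomposition.e3_anchor, decomposition.poi_anchor, elements
    )
    L = link_pct / 100.0 * d_link
    lo = 100.0 * abs(L - d_e3 - d_poi) / d_max
    hi = 100.0 * (L + d_e3 + d_poi) / d_max
    return lo, min(hi, 110.0)


def generate_conformer_ensemble(
    record: ProtacRecord,
    decomposition: Decomposition,
    contraction_targets: Sequence,
    seed: int = 0,
    solvent: str = "none",
    energy_mean_kjmol: float = 5.0,
    energy_window_kjmol: float = 21.0,
) -> tuple:
    """Conformers with exactly prescribed molecule/linker contraction.

    ``contraction_targets`` is a sequence of ``(molecule_pct, linker_pct)``
    pairs in (0, 110], one per conformer.  The E3 and POI domains are rigid
    bodies hinged at the anchors: the anchor separation realises the linker
    target and the two domain-COM directions are folded symmetrically until
    the COM-COM distance realises the molecule target.  Seeded rigid jitter
    (rotations about the hinge axes plus a global rotation/translation)
    varies the coordinates without moving either realized value.  Relative
    energies are drawn from a truncated exponential (mean 5 kJ/mol, window
    21 kJ/mol) and shifted to minimum 0.
    """
    rng = _rng(seed)
    mol = mol_from_smiles(record.smiles)
    molh, xy = geometry.layout_2d(mol)
    n_heavy = mol.GetNumAtoms()
    elements = [a.GetSymbol() for a in molh.GetAtoms()]
    masses = np.array([ATOMIC_MASS[e] for e in elements])
    domains = list(decomposition.atom_domains)
    for atom in molh.GetAtoms():
        if atom.GetIdx() >= n_heavy:  # hydrogens appended after heavy atoms
            domains.append(domains[atom.GetNeighbors()[0].GetIdx()])
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in molh.GetBonds()]

    a1, a2 = decomposition.e3_anchor, decomposition.poi_anchor
    d_e3, d_link, d_poi, d_max = geometry.max_extended_distance_2d(
        xy, masses, domains, a1, a2, elements
    )
    e3_idx = [i for i, d in enumerate(domains) if d == "e3"]
    poi_idx = [i for i, d in enumerate(domains) if d == "poi"]
    link_idx = [i for i, d in enumerate(domains) if d == "linker"]
    com_e3_2d = geometry.center_of_mass(xy, masses, e3_idx)
    com_poi_2d = geometry.center_of_mass(xy, masses, poi_idx)

    coords_list = []
    truths = []
    for mol_pct, link_pct in contraction_targets:
        if not (0 < mol_pct <= 110) or not (0 < link_pct <= 110):
            raise InfeasibleTarget("contraction targets must lie in (0, 110]")
        L = link_pct / 100.0 * d_link
        D = mol_pct / 100.0 * d_max
        lo, hi = abs(L - d_e3 - d_poi), L + d_e3 + d_poi
        if not (lo - 1e-9 <= D <= hi + 1e-9):
            raise InfeasibleTarget(
                f"COM distance {D:.2f} A unreachable with anchors {L:.2f} A apart "
                f"(feasible range {lo:.2f}-{hi:.2f} A)"
            )

        def com_distance(alpha, L=L):
            s, c = np.sin(alpha), np.cos(alpha)
            dx = L + (d_e3 + d_poi) * c
            dz = (d_poi - d_e3) * s
            return float(np.hypot(dx, dz))

        if com_distance(0.0) <= D:
            alpha = 0.0
        elif com_distance(np.pi) >= D:
            alpha = np.pi
        else:
            alpha = brentq(lambda a: com_distance(a) - D, 0.0, np.pi, xtol=1e-14)
        s, c = np.sin(alpha), np.cos(alpha)
        u1 = np.array([-c, 0.0, s])  # anchor1 -> E3 COM direction
        u2 = np.array([c, 0.0, s])  # anchor2 -> POI COM direction
        anchor1 = np.zeros(3)
        anchor2 = np.array([L, 0.0, 0.0])

        xyz = np.zeros((len(elements), 3))
        # rigid E3 body
        body = xy[e3_idx] - xy[a1]
        rot = _rotation_between(com_e3_2d - xy[a1], u1)
        jit = _axis_rotation(u1, rng.uniform(0, 2 * np.pi))
        xyz[e3_idx] = (jit @ rot @ body.T).T + anchor1
        # rigid POI body
        body = xy[poi_idx] - xy[a2]
        rot = _rotation_between(com_poi_2d - xy[a2], u2)
        jit = _axis_rotation(u2, rng.uniform(0, 2 * np.pi))
        xyz[poi_idx] = (jit @ rot @ body.T).T + anchor2
        # linker: similarity map of the 2D layout onto the anchor segment
        if link_idx:
            scale = L / d_link if d_link > 0 else 1.0
            rot = _rotation_between(xy[a2] - xy[a1], anchor2 - anchor1)
            jit = _axis_rotation(
                anchor2 - anchor1 if L > 0 else np.array([1.0, 0, 0]),
                rng.uniform(0, 2 * np.pi),
            )
            xyz[link_idx] = (jit @ rot @ ((xy[link_idx] - xy[a1]) * scale).T).T + anchor1
        # global rigid jitter
        gr = _axis_rotation(rng.normal(size=3), rng.uniform(0, 2 * np.pi))
        xyz = (gr @ xyz.T).T + rng.normal(scale=5.0, size=3)
        coords_list.append(xyz)
        truths.append({"molecule_contraction": mol_pct, "linker_contraction": link_pct})

    energies = _truncated_exponential(
        rng, len(coords_list), energy_mean_kjmol, energy_window_kjmol
    )
    energies -= energies.min()
    ensemble = ConformerEnsemble(
        elements=elements,
        masses=masses,
        domains=domains,
        coords=coords_list,
        energies=energies,
        solvent=solvent,
        bonds=bonds,
    )
    truth = GroundTruth(
        seed=seed,
        params={"record_id": record.id, "n_conformers": len(coords_list)},
        values={
            "per_conformer": truths,
            "d_max_2d": d_max,
            "d_linker_2d": d_link,
            "e3_anchor": a1,
            "poi_anchor": a2,
        },
    )
    return ensemble, truth


# ---------------------------------------------------------------------------
# Parametric free-energy profiles
# ---------------------------------------------------------------------------


@dataclass
class ProfileArchetype:
    """Parametric membrane profile: interface wells + core barrier (kJ/mol)."""

    depth_min: float = 20.0
    z_min: float = 15.0
    barrier_core: float = 30.0
    well_width: float = 4.0
    core_width: float = 3.0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.well_width <= 0 or self.core_width <= 0:
            raise InvalidGrid("widths must be positive")
        if self.noise_sigma < 0:
            raise InvalidGrid("noise_sigma must be non-negative")

    def noise_free(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        wells = np.exp(-((z - self.z_min) ** 2) / (2 * self.well_width**2)) + np.exp(
            -((z + self.z_min) ** 2) / (2 * self.well_width**2)
        )
        core = np.exp(-(z**2) / (2 * self.core_width**2))
        return -self.depth_min * wells + self.barrier_core * core


# Two cluster families: a strong interface binder with a modest core barrier,
# and a shallow binder blocked by a high core barrier.
ARCHETYPE_INTERFACE_BINDER = ProfileArchetype(
    depth_min=25.0, z_min=15.0, barrier_core=12.0
)
ARCHETYPE_CORE_BLOCKED = ProfileArchetype(depth_min=8.0, z_min=16.0, barrier_core=45.0)


def true_barriers(
    archetype: ProfileArchetype,
    interface_min_z: float = 5.0,
    water_region_cutoff: float = 30.0,
    z_max: float = 35.0,
):
    """Analytic (dense-grid) BarrierSet of the noise-free form.

    The noise-free profile is referenced the same way the analysis
    normalises: zero mean over |z| >= cutoff.
    """
    dense = np.arange(-z_max, z_max + 1e-9, 0.001)
    g = archetype.noise_free(dense)
    g = g - g[np.abs(dense) >= water_region_cutoff].mean()
    region = (np.abs(dense) >= interface_min_z) & (np.abs(dense) <= water_region_cutoff)
    slope_bound = float(np.max(np.abs(np.gradient(g, dense))[region]))
    i = int(np.argmin(np.where(region, g, np.inf)))
    g_min = float(g[i])
    g_core = float(g[np.argmin(np.abs(dense))])
    if g_min >= 0:
        return {"z_min": None, "depth_min": 0.0, "barrier_min_to_core": g_core,
                "barrier_min_to_water": 0.0, "max_abs_slope_interface": slope_bound}
    return {
        "z_min": float(dense[i]),
        "depth_min": -g_min,
        "barrier_min_to_core": g_core - g_min,
        "barrier_min_to_water": -g_min,
        "max_abs_slope_interface": slope_bound,
    }


def generate_profiles(
    archetype: ProfileArchetype,
    n_conformers: int,
    grid: ProfileGrid | None = None,
    seed: int = 0,
    temperature: float = 310.0,
) -> tuple:
    """Symmetric conformer profiles from an archetype plus Gaussian noise.

    Returns ``(profiles, GroundTruth)``; the truth holds the analytic
    BarrierSet of the noise-free form.
    """
    grid = grid or ProfileGrid()
    rng = _rng(seed)
    z = grid.z
    base = archetype.noise_free(z)
    profiles = []
    for k in range(n_conformers):
        noise = rng.normal(scale=archetype.noise_sigma, size=z.shape) if archetype.noise_sigma else 0.0
        profiles.append(
            FreeEnergyProfile(
                z=z, g=base + noise, temperature=temperature, meta={"conformer": k}
            )
        )
    truth = GroundTruth(
        seed=seed,
        params={k: v for k, v in asdict(archetype).items()},
        values={"barriers": true_barriers(archetype, z_max=grid.z_max)},
    )
    return profiles, truth


# ---------------------------------------------------------------------------
# Orientation states
# ---------------------------------------------------------------------------


def generate_orientation_states(
    group_probs: dict,
    n_states: int,
    seed: int = 0,
    z_range: tuple = (0.0, 35.0),
):
    """Geometrically consistent states with a prescribed group distribution.

    ``group_probs`` maps group indices to probabilities (renormalised over
    the given, geometrically feasible groups).  Each state is realised by
    rejection-sampling a pair of uniform random unit vectors until its group
    matches the drawn target, so all three angles always satisfy the
    spherical constraints.
    """
    from .orientation import OrientationState, assign_group, orientation_angles

    rng = _rng(seed)
    groups = sorted(group_probs)
    p = np.array([group_probs[g] for g in groups], dtype=float)
    p /= p.sum()
    targets = rng.choice(groups, size=n_states, p=p)
    states = []
    for target in targets:
        for _ in range(200_000):
            u = rng.normal(size=3)
            v = rng.normal(size=3)
            state = orientation_angles(u, v, z=rng.uniform(*z_range))
            if assign_group(state).index == int(target):
                states.append(state)
                break
        else:
            raise InvalidTruth(
                f"group {int(target)} appears geometrically infeasible "
                "(spherical triangle constraints exclude some section triples)"
            )
    truth = GroundTruth(
        seed=seed,
        params={"n_states": n_states},
        values={"group_probs": {int(g): float(w) for g, w in zip(groups, p)}},
    )
    return states, truth


# ---------------------------------------------------------------------------
# Assay data
# ---------------------------------------------------------------------------


def generate_dialysis_data(
    fu: float,
    noise_cv: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    nominal_conc: float = 0.1,
    lloq: float = 0.001,
):
    """Dialysis replicates from a true unbound fraction.

    ``c_buffer = fu * c_homogenate * (1 + eps)`` with multiplicative
    lognormal noise of the given CV on both chambers.
    """
    if not 0 < fu <= 1:
        raise InvalidTruth("fu must be in (0, 1]")
    if noise_cv < 0:
        raise InvalidTruth("noise_cv must be non-negative")
    rng = _rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    out = []
    for r in range(n_replicates):
        noise = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=2) if sigma else np.ones(2)
        out.append(
            DialysisMeasurement(
                c_homogenate=nominal_conc * noise[0],
                c_buffer=fu * nominal_conc * noise[1],
                lloq=lloq,
                replicate=f"rep{r + 1}",
                nominal_conc=nominal_conc,
            )
        )
    truth = GroundTruth(seed=seed, params={"noise_cv": noise_cv}, values={"fu": fu})
    return out, truth


def simulate_transport(
    papp_true: float,
    d0: float = 10.0,
    v_donor_ml: float = 0.2,
    v_receiver_ml: float = 0.8,
    v_withdraw_ml: float = 0.1,
    v_donor_sample_ml: float = 0.01,
    area_cm2: float = 0.33,
    times_min: Sequence[float] = (45.0, 120.0),
):
    """Exact two-compartment forward simulation of an A-B transport assay.

    Flux J = Papp * A * (C_D - C_R); chamber volumes held constant; at each
    sampling time the receiver loses ``v_withdraw_ml`` (replaced with fresh
    buffer) and the donor loses the ``v_donor_sample_ml`` sample, exactly the
    amounts the printed recovery equation books.  D0 is the donor
    concentration after the time-zero sample.  Returns per-time donor and
    receiver concentrations (sampled just before the withdrawals).
    """
    k = papp_true * area_cm2  # cm^3/s == mL/s
    kappa = k * (1.0 / v_donor_ml + 1.0 / v_receiver_ml)
    a_d, a_r = d0 * v_donor_ml, 0.0
    t_prev = 0.0
    donor, receiver = [], []
    for t in times_min:
        dt = (t - t_prev) * 60.0
        x0 = a_d / v_donor_ml - a_r / v_receiver_ml
        if kappa > 0:
            transferred = k * x0 * (1.0 - np.exp(-kappa * dt)) / kappa
        else:
            transferred = 0.0
        a_d -= transferred
        a_r += transferred
        cd, cr = a_d / v_donor_ml, a_r / v_receiver_ml
        donor.append(cd)
        receiver.append(cr)
        a_r -= cr * v_withdraw_ml  # replaced with fresh buffer, volume constant
        a_d -= cd * v_donor_sample_ml
        t_prev = t
    return np.array(donor), np.array(receiver)


def generate_transport_data(
    papp_true: float,
    noise_cv: float = 0.0,
    seed: int = 0,
    d0: float = 10.0,
    times_min: Sequence[float] = (45.0, 120.0),
    **geometry_kwargs,
):
    """A TransportExperiment forward-simulated from a true Papp."""
    if papp_true < 0:
        raise InvalidTruth("papp must be non-negative")
    if noise_cv < 0:
        raise InvalidTruth("noise_cv must be non-negative")
    rng = _rng(seed)
    donor, receiver = simulate_transport(
        papp_true, d0=d0, times_min=times_min, **geometry_kwargs
    )
    if noise_cv:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        donor = donor * rng.lognormal(-sigma**2 / 2, sigma, donor.shape)
        receiver = receiver * rng.lognormal(-sigma**2 / 2, sigma, receiver.shape)
    exp = TransportExperiment(
        times_min=list(times_min),
        receiver_conc=receiver.tolist(),
        d0=d0,
        donor_conc=donor.tolist(),
        **geometry_kwargs,
    )
    truth = GroundTruth(
        seed=seed,
        params={"noise_cv": noise_cv, "d0": d0},
        values={"papp": papp_true},
    )
    return exp, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def generate_cohort(n: int, seed: int = 0) -> list:
    """Assemble ``n`` PROTACs cycling through the fragment libraries.

    Returns a list of ``(ProtacRecord, GroundTruth)`` pairs covering every
    E3 core, linker motif and POI ligand combination in a fixed order.
    """
    libs = fragment_libraries()
    e3_names = sorted(libs["e3_ligands"])
    linker_names = sorted(libs["linkers"])
    poi_names = sorted(libs["poi_ligands"])
    out = []
    for i in range(n):
        e3 = e3_names[i % len(e3_names)]
        linker = linker_names[(i // len(e3_names)) % len(linker_names)]
        poi = poi_names[i % len(poi_names)]
        record, truth = assemble_protac(
            libs["e3_ligands"][e3],
            libs["linkers"][linker],
            libs["poi_ligands"][poi],
            record_id=f"synthetic-{i:03d}",
            e3_class=libs["e3_classes"][e3],
        )
        truth.seed = seed
        truth.params.update({"e3_name": e3, "linker_name": linker, "poi_name": poi})
        out.append((record, truth))
    return out
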