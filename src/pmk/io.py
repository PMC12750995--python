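"""Readers and writers for the package's interchange formats."""

from __future__ import annotations

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Geometry import Point3D

from .profiles import FreeEnergyProfile

__all__ = [
    "read_smiles_table",
    "read_profiles_csv",
    "write_profiles_csv",
    "write_conformers_sdf",
    "read_conformers_sdf",
]


def read_smiles_table(path) -> pd.DataFrame:
    """One record per line, ``id<TAB>smiles``; '#' comments allowed."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"expected 'id<TAB>smiles', got {line!r}")
            rows.append({"id": parts[0], "smiles": parts[1]})
    return pd.DataFrame(rows)


def read_profiles_csv(path, temperature: float = 310.0) -> dict:
    """Long-format profile CSV ``id,conf,z_angstrom,g_kjmol`` -> profiles.

    Returns ``{(id, conf): FreeEnergyProfile}`` with rows sorted by z.
    """
    df = pd.read_csv(path)
    out = {}
    for (pid, conf), grp in df.groupby(["id", "conf"]):
        grp = grp.sort_values("z_angstrom")
        out[(pid, conf)] = FreeEnergyProfile(
            z=grp["z_angstrom"].to_numpy(),
            g=grp["g_kjmol"].to_numpy(),
            temperature=temperature,
            meta={"id": pid, "conf": conf},
        )
    return out


def write_profiles_csv(profiles: dict, path) -> None:
    """Inverse of :func:`read_profiles_csv`."""
    rows = []
    for (pid, conf), p in profiles.items():
        for z, g in zip(p.z, p.g):
            rows.append({"id": pid, "conf": conf, "z_angstrom": z, "g_kjmol": g})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_conformers_sdf(record_id: str, smiles: str, ensemble, fh) -> None:
    """Append an ensemble as a multi-record SDF (one record per conformer).

    Atom order is the parse order of ``smiles`` with explicit hydrogens
    appended, matching the ensemble layout.  Each record carries ``id``,
    ``conf`` and the relative energy tag ``E_rel_kJmol``.
    """
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    if mol.GetNumAtoms() != len(ensemble.elements):
        raise ValueError("ensemble does not match the molecule's atom count")
    writer = Chem.SDWriter(fh)
    writer.SetKekulize(True)
    for k, xyz in enumerate(ensemble.coords):
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, (x, y, z) in enumerate(np.asarray(xyz, dtype=float)):
            conf.SetAtomPosition(i, Point3D(x, y, z))
        m = Chem.Mol(mol)
        m.RemoveAllConformers()
        m.AddConformer(conf, assignId=True)
        m.SetProp("id", record_id)
        m.SetProp("conf", str(k))
        m.SetProp("E_rel_kJmol", f"{ensemble.energies[k]:.6f}")
        writer.write(m)
    writer.flush()


def read_conformers_sdf(path) -> dict:
    """Multi-conformer SDF -> {id: (mol_with_h, [(coords, energy_kJmol)])}."""
    out: dict = {}
    for mol in Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True):
        if mol is None:
            continue
        pid = mol.GetProp("id") if mol.HasProp("id") else mol.GetProp("_Name")
        energy = float(mol.GetProp("E_rel_kJmol")) if mol.HasProp("E_rel_kJmol") else 0.0
        conf = mol.GetConformer()
        xyz = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
        out.setdefault(pid, (mol, []))[1].append((xyz, energy))
    return out
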