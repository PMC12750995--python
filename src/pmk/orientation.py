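"""Depth-resolved molecular-orientation classification.

With the linker center of mass at the origin, three angles describe how a
PROTAC sits relative to the membrane normal: (1) normal vs the linker-to-E3
vector, (2) normal vs the linker-to-POI vector, (3) between the two domain
vectors.  Each angle (0-180 degrees) is split into three 60-degree sections,
giving 27 orientation groups; per-depth group distributions summarise the
preferred orientations across the bilayer.  Centers of mass exclude
hydrogens here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDomain, EmptyInput, ZeroVector
from .geometry import ConformerEnsemble, center_of_mass

__all__ = [
    "OrientationState",
    "OrientationGroup",
    "MEMBRANE_NORMAL",
    "domain_vectors",
    "orientation_angles",
    "assign_group",
    "depth_distribution",
    "label_schematic",
]

MEMBRANE_NORMAL = np.array([0.0, 0.0, 1.0])


@dataclass
class OrientationState:
    angle_normal_e3: float
    angle_normal_poi: float
    angle_e3_poi: float
    z: float = float("nan")  # depth of the linker COM


@dataclass(frozen=True)
class OrientationGroup:
    """Triple of 60-degree sections, bijectively indexed 9*s1 + 3*s2 + s3."""

    s1: int
    s2: int
    s3: int

    @property
    def index(self) -> int:
        return 9 * self.s1 + 3 * self.s2 + self.s3

    @classmethod
    def from_index(cls, index: int) -> "OrientationGroup":
        if not 0 <= index <= 26:
            raise ValueError("group index must be in [0, 26]")
        return cls(index // 9, (index // 3) % 3, index % 3)


def domain_vectors(ensemble: ConformerEnsemble, conformer: int):
    """Vectors from the linker COM (translated to the origin) to the E3 and
    POI centers of mass, hydrogens excluded.

    For an empty linker the midpoint of the two anchor atoms stands in for
    the linker COM; pass the anchors via ``ensemble.domains`` labelling or a
    precomputed origin in that case.
    """
    xyz = ensemble.coords[conformer]
    out = {}
    for domain in ("e3", "poi", "linker"):
        idx = ensemble.domain_atoms(domain)
        heavy = [i for i in idx if ensemble.elements[i] != "H"]
        if domain == "linker" and not heavy:
            out["linker"] = None
            continue
        if not heavy:
            raise DegenerateDomain(f"domain {domain!r} has no heavy atoms")
        out[domain] = center_of_mass(
            xyz, ensemble.masses, heavy, ensemble.elements, exclude_hydrogens=True
        )
    origin = out["linker"]
    if origin is None:
        raise DegenerateDomain(
            "empty linker: supply the anchor-bond midpoint as the origin"
        )
    return out["e3"] - origin, out["poi"] - origin


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ZeroVector("orientation vectors must be non-zero")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def orientation_angles(
    e3_vector: np.ndarray,
    poi_vector: np.ndarray,
    membrane_normal: np.ndarray = MEMBRANE_NORMAL,
    z: float = float("nan"),
) -> OrientationState:
    """The three inter-vector angles in degrees, each in [0, 180]."""
    e3_vector = np.asarray(e3_vector, dtype=float)
    poi_vector = np.asarray(poi_vector, dtype=float)
    membrane_normal = np.asarray(membrane_normal, dtype=float)
    return OrientationState(
        angle_normal_e3=_angle_deg(membrane_normal, e3_vector),
        angle_normal_poi=_angle_deg(membrane_normal, poi_vector),
        angle_e3_poi=_angle_deg(e3_vector, poi_vector),
        z=z,
    )


def _section(angle: float) -> int:
    """0: [0, 60), 1: [60, 120), 2: [120, 180] (180 closed into 2)."""
    if not 0.0 <= angle <= 180.0:
        raise ValueError("angle must be within [0, 180]")
    return min(int(angle // 60), 2)


def assign_group(state: OrientationState) -> OrientationGroup:
    """Map the three angles onto one of the 27 orientation groups."""
    return OrientationGroup(
        _section(state.angle_normal_e3),
        _section(state.angle_normal_poi),
        _section(state.angle_e3_poi),
    )


def depth_distribution(
    states: Sequence[OrientationState],
    depth_bins: Sequence[float],
) -> pd.DataFrame:
    """Fraction of states in each of the 27 groups per depth bin.

    ``depth_bins`` are bin edges on |z| or signed z; fractions sum to 1 in
    every non-empty bin.  Returns a tidy frame (depth_bin, group, fraction).
    """
    if len(states) == 0:
        raise EmptyInput("no orientation states")
    z = np.array([s.z for s in states])
    groups = np.array([assign_group(s).index for s in states])
    edges = np.asarray(depth_bins, dtype=float)
    which = np.digitize(z, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        mask = which == b
        total = mask.sum()
        if total == 0:
            continue
        counts = np.bincount(groups[mask], minlength=27)
        for gi in range(27):
            rows.append(
                {
                    "depth_bin": f"[{edges[b]:g},{edges[b + 1]:g})",
                    "group": gi,
                    "fraction": counts[gi] / total,
                }
            )
    return pd.DataFrame(rows)


# Schematic orientation labels.  Section 0 points along +normal (toward
# water), section 2 toward the membrane core.
def label_schematic(group: OrientationGroup) -> str:
    """Deterministic schematic label for a group.

    (0,2,*): E3 out / POI in, extended -> extended_poi_in; (2,0,*) the
    mirror; both domain angles mid-section -> flat; (0,0,*)/(2,2,*) both
    domains pointing the same way -> bent; anything else -> other.
    """
    s1, s2 = group.s1, group.s2
    if s1 == 0 and s2 == 2:
        return "extended_poi_in"
    if s1 == 2 and s2 == 0:
        return "extended_e3_in"
    if s1 == 1 and s2 == 1:
        return "flat"
    if s1 == 0 and s2 == 0:
        return "bent_both_out"
    if s1 == 2 and s2 == 2:
        return "bent_both_in"
    return "other"
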