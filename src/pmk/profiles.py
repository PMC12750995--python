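"""Depth-resolved membrane free-energy-profile analytics.

A free-energy profile G(z) gives the solvation free energy of a solute as a
function of the signed distance z (Angstrom) from the lipid-bilayer core
(z = 0), referenced to bulk water.  This module normalises profiles to the
bulk-water region, interpolates them onto a common symmetric grid, combines
per-conformer profiles into a Boltzmann ensemble profile, extracts the
interface minimum and the barriers out of it (toward the membrane core and
back to water), converts barriers into Boltzmann occupancy ratios, clusters
profiles by complete-linkage hierarchical clustering, and provides the
ordinary-least-squares barrier-vs-affinity regression and three-way
permeability binning used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.signal import savgol_filter
from scipy.special import logsumexp

from .errors import (
    DegenerateInput,
    GridMismatch,
    InsufficientRange,
    InvalidGrid,
    InvalidThresholds,
    NotNormalized,
    OutOfRange,
)

__all__ = [
    "R_KJ_PER_MOL_K",
    "FreeEnergyProfile",
    "BarrierSet",
    "ProfileGrid",
    "normalize_profile",
    "interpolate_to_grid",
    "boltzmann_ensemble",
    "average_profiles",
    "extract_barriers",
    "occupancy_ratio",
    "cluster_profiles",
    "regress_barrier_vs_affinity",
    "classify_permeability",
]

R_KJ_PER_MOL_K = 8.314e-3  # gas constant, kJ/(mol K)


@dataclass
class FreeEnergyProfile:
    """G(z) in kJ/mol on strictly increasing z (Angstrom from the core)."""

    z: np.ndarray
    g: np.ndarray
    temperature: float = 310.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.z.ndim != 1 or self.z.shape != self.g.shape:
            raise ValueError("z and g must be 1-D arrays of equal length")
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z must be strictly increasing")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("g must be finite")


@dataclass
class BarrierSet:
    """Interface-minimum location and the barriers out of it (kJ/mol)."""

    z_min: float | None
    depth_min: float
    barrier_min_to_core: float
    barrier_min_to_water: float

    @property
    def dominant_barrier(self) -> float:
        return max(self.barrier_min_to_core, self.barrier_min_to_water)

    @property
    def dominant_kind(self) -> str:
        return (
            "to_core"
            if self.barrier_min_to_core >= self.barrier_min_to_water
            else "to_water"
        )


@dataclass
class ProfileGrid:
    """Uniform symmetric z grid; reference slice thickness ~1 A (0.1 nm)."""

    z_max: float = 35.0
    slice_thickness: float = 1.0

    def __post_init__(self) -> None:
        if self.z_max <= 0 or self.slice_thickness <= 0:
            raise InvalidGrid("z_max and slice_thickness must be positive")
        n = round(self.z_max / self.slice_thickness)
        if abs(n * self.slice_thickness - self.z_max) > 1e-9:
            raise InvalidGrid("z_max must be a multiple of slice_thickness")

    @property
    def z(self) -> np.ndarray:
        n = round(self.z_max / self.slice_thickness)
        return np.linspace(-self.z_max, self.z_max, 2 * n + 1)


def _common_grid(profiles: Sequence[FreeEnergyProfile]) -> np.ndarray:
    z0 = profiles[0].z
    for p in profiles[1:]:
        if p.z.shape != z0.shape or not np.allclose(p.z, z0):
            raise GridMismatch("profiles are not on a common z grid")
    return z0


def normalize_profile(
    profile: FreeEnergyProfile, water_region_cutoff: float = 30.0
) -> FreeEnergyProfile:
    """Shift G so its mean over the bulk-water region |z| >= cutoff is zero."""
    tail = np.abs(profile.z) >= water_region_cutoff
    if not tail.any() or profile.z.min() > -water_region_cutoff or profile.z.max() < water_region_cutoff:
        raise InsufficientRange(
            f"profile does not reach |z| >= {water_region_cutoff} on both sides"
        )
    return replace(profile, g=profile.g - profile.g[tail].mean())


def interpolate_to_grid(
    profiles: Sequence[FreeEnergyProfile], grid: ProfileGrid | np.ndarray
) -> list:
    """Piecewise-linear interpolation of each profile onto a common grid."""
    z_new = grid.z if isinstance(grid, ProfileGrid) else np.asarray(grid, dtype=float)
    out = []
    for p in profiles:
        if z_new.min() < p.z.min() - 1e-9 or z_new.max() > p.z.max() + 1e-9:
            raise OutOfRange("grid exceeds the profile's z range")
        out.append(replace(p, z=z_new, g=np.interp(z_new, p.z, p.g)))
    return out


def boltzmann_ensemble(
    conformer_profiles: Sequence[FreeEnergyProfile],
    temperature: float = 310.0,
):
    """Per-slice Boltzmann combination of conformer profiles.

    G_ens(z) = -RT ln[(1/N) sum_i exp(-G_i(z)/RT)] with a uniform prior over
    the N conformers.  Also returns the per-slice conformer weights
    w_i(z) = exp(-G_i(z)/RT) / sum_j exp(-G_j(z)/RT), which sum to 1 in every
    slice.  G_ens is bounded by min_i G_i and min_i G_i + RT ln N.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    z = _common_grid(conformer_profiles)
    rt = R_KJ_PER_MOL_K * temperature
    gmat = np.vstack([p.g for p in conformer_profiles])  # (N, nz)
    n = gmat.shape[0]
    log_z = logsumexp(-gmat / rt, axis=0)  # per slice
    g_ens = -rt * (log_z - np.log(n))
    weights = np.exp(-gmat / rt - log_z[None, :])
    ens = FreeEnergyProfile(
        z=z, g=g_ens, temperature=temperature, meta={"n_conformers": n}
    )
    return ens, weights


def average_profiles(
    profiles: Sequence[FreeEnergyProfile], method: str = "mean"
) -> FreeEnergyProfile:
    """Per-slice mean (across snapshots) or median (across compounds)."""
    z = _common_grid(profiles)
    gmat = np.vstack([p.g for p in profiles])
    if method == "mean":
        g = gmat.mean(axis=0)
    elif method == "median":
        g = np.median(gmat, axis=0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return FreeEnergyProfile(
        z=z, g=g, temperature=profiles[0].temperature, meta={"method": method}
    )


def extract_barriers(
    profile: FreeEnergyProfile,
    interface_min_z: float = 5.0,
    water_region_cutoff: float = 30.0,
    smooth_window: int = 5,
    normalization_tol: float = 1e-6,
) -> BarrierSet:
    """Interface minimum and the barriers leaving it.

    The profile must be bulk-water referenced (mean ~0 over |z| >= cutoff).
    The minimum is searched in interface_min_z <= |z| <= cutoff; the two
    leaflet minima reduce to the deeper one.  G at the core is read at z = 0
    exactly.  A short Savitzky-Golay smoother (quadratic, default window 5)
    suppresses per-slice noise before the extremum search; window 1 disables
    it.  With no minimum below zero, depth is 0 and z_min undefined; barriers
    are then measured from the bulk-water level.
    """
    z, g = profile.z, profile.g
    tail = np.abs(z) >= water_region_cutoff
    if not tail.any():
        raise NotNormalized("profile does not reach the bulk-water region")
    if abs(g[tail].mean()) > normalization_tol:
        raise NotNormalized("profile is not referenced to bulk water (mean tail != 0)")
    core = np.argmin(np.abs(z))
    if abs(z[core]) > 1e-9:
        raise InvalidGrid("grid must contain z = 0")
    if smooth_window > 1 and len(g) >= smooth_window:
        gs = savgol_filter(g, smooth_window, 2)
    else:
        gs = g
    region = (np.abs(z) >= interface_min_z) & (np.abs(z) <= water_region_cutoff)
    g_region = np.where(region, gs, np.inf)
    i_min = int(np.argmin(g_region))
    g_min = float(gs[i_min])
    g_core = float(gs[core])
    if g_min < 0:
        z_min: float | None = float(z[i_min])
        depth = -g_min
    else:
        z_min = None
        depth = 0.0
        g_min = 0.0
    return BarrierSet(
        z_min=z_min,
        depth_min=depth,
        barrier_min_to_core=g_core - g_min,
        barrier_min_to_water=-g_min,
    )


def occupancy_ratio(delta_g: float, temperature: float = 310.0) -> float:
    """Boltzmann occupancy ratio exp(-dG/RT) for dG in kJ/mol."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return float(np.exp(-delta_g / (R_KJ_PER_MOL_K * temperature)))


def cluster_profiles(profiles: Sequence[FreeEnergyProfile], n_clusters: int):
    """Complete-linkage hierarchical clustering of profile vectors.

    Euclidean distance on the G(z) vectors; labels are renumbered by first
    occurrence so the partition is independent of input order up to label
    names.  Returns ``(labels, linkage_matrix)``.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    _common_grid(profiles)
    gmat = np.vstack([p.g for p in profiles])
    if len(profiles) == 1:
        return np.zeros(1, dtype=int), np.empty((0, 4))
    lm = linkage(gmat, method="complete", metric="euclidean")
    raw = fcluster(lm, t=n_clusters, criterion="maxclust")
    labels = np.empty_like(raw)
    mapping: dict = {}
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping)
        labels[i] = mapping[r]
    return labels, lm


def regress_barrier_vs_affinity(x: Sequence[float], y: Sequence[float]):
    """Ordinary least squares y ~ x: (slope, intercept, r_squared)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise DegenerateInput("need at least 3 points")
    if np.ptp(x) == 0:
        raise DegenerateInput("x is constant")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def classify_permeability(
    papp_values: Sequence[float],
    thresholds: tuple = (1e-6, 10e-6),
) -> list:
    """Three-way Papp binning (cm/s); boundary values go to the upper class.

    The default cutoffs 1e-6 / 10e-6 cm/s are package defaults, not
    literature-prescribed values.
    """
    low, high = thresholds
    if not low < high:
        raise InvalidThresholds("thresholds must satisfy low < high")
    out = []
    for p in papp_values:
        if p >= high:
            out.append("high")
        elif p >= low:
            out.append("moderate")
        else:
            out.append("low")
    return out
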