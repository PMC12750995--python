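"""Free-energy-profile normalisation, Boltzmann combination and barriers."""

import numpy as np
import pytest

from pmk import profiles as pr
from pmk.errors import (
    DegenerateInput,
    GridMismatch,
    InsufficientRange,
    InvalidThresholds,
    NotNormalized,
    OutOfRange,
)
from pmk.profiles import FreeEnergyProfile, ProfileGrid

RT310 = pr.R_KJ_PER_MOL_K * 310.0
GRID = ProfileGrid().z


def profile(g, z=None, **kw):
    return FreeEnergyProfile(z=GRID if z is None else z, g=np.broadcast_to(g, (GRID if z is None else np.asarray(z)).shape).copy(), **kw)


class TestGrid:
    def test_symmetric_and_contains_zero(self):
        z = ProfileGrid(z_max=35, slice_thickness=1.0).z
        assert np.allclose(z, -z[::-1])
        assert 0.0 in z
        assert z.max() >= 35


class TestNormalize:
    def test_constant_becomes_zero(self):
        out = pr.normalize_profile(profile(7.0))
        assert np.allclose(out.g, 0.0)

    def test_shift_invariance(self):
        rng = np.random.Generator(np.random.Philox(1))
        g = rng.normal(size=GRID.shape)
        a = pr.normalize_profile(FreeEnergyProfile(GRID, g))
        b = pr.normalize_profile(FreeEnergyProfile(GRID, g + 7.0))
        assert np.allclose(a.g, b.g)

    def test_mean_over_both_tails(self):
        g = np.where(GRID <= -30, 4.0, np.where(GRID >= 30, 8.0, 0.0))
        out = pr.normalize_profile(FreeEnergyProfile(GRID, g))
        tail = np.abs(GRID) >= 30
        assert out.g[tail].mean() == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_range(self):
        z = np.linspace(-10, 10, 21)
        with pytest.raises(InsufficientRange):
            pr.normalize_profile(FreeEnergyProfile(z, np.zeros(21)))


class TestInterpolate:
    def test_identity_on_grid(self):
        p = profile(0.0)
        p = FreeEnergyProfile(GRID, np.sin(GRID))
        (out,) = pr.interpolate_to_grid([p], ProfileGrid())
        assert np.allclose(out.g, p.g)

    def test_linear_function_exact(self):
        coarse = np.linspace(-40, 40, 9)
        p = FreeEnergyProfile(coarse, 2.0 * coarse)
        (out,) = pr.interpolate_to_grid([p], ProfileGrid())
        assert np.allclose(out.g, 2.0 * GRID)

    def test_matches_two_point_formula(self):
        rng = np.random.Generator(np.random.Philox(2))
        z = np.sort(rng.uniform(-40, 40, size=37))
        g = rng.normal(size=37)
        p = FreeEnergyProfile(z, g)
        targets = rng.uniform(z.min(), z.max(), size=25)
        targets.sort()
        (out,) = pr.interpolate_to_grid([p], targets)
        for zt, gt in zip(targets, out.g):
            j = np.searchsorted(z, zt)
            j = max(1, min(j, len(z) - 1))
            frac = (zt - z[j - 1]) / (z[j] - z[j - 1])
            assert gt == pytest.approx(g[j - 1] + frac * (g[j] - g[j - 1]), abs=1e-12)

    def test_out_of_range(self):
        p = FreeEnergyProfile(np.linspace(-20, 20, 11), np.zeros(11))
        with pytest.raises(OutOfRange):
            pr.interpolate_to_grid([p], ProfileGrid())


class TestBoltzmann:
    def test_identical_profiles_unchanged(self):
        p = FreeEnergyProfile(GRID, np.sin(GRID / 5) * 10)
        ens, w = pr.boltzmann_ensemble([p, p, p], 310.0)
        assert np.allclose(ens.g, p.g, atol=1e-10)
        assert np.allclose(w, 1 / 3)

    def test_dominated_profile_ignored(self):
        lo = FreeEnergyProfile(GRID, np.cos(GRID / 7) * 5)
        hi = FreeEnergyProfile(GRID, lo.g + 1000.0)
        ens, _ = pr.boltzmann_ensemble([lo, hi], 310.0)
        assert np.allclose(ens.g, lo.g + RT310 * np.log(2), atol=1e-6)

    def test_partition_sum_analytic_case(self):
        z = np.array([0.0, 1.0])
        p1 = FreeEnergyProfile(z, np.zeros(2))
        p2 = FreeEnergyProfile(z, np.full(2, RT310 * np.log(3)))
        ens, w = pr.boltzmann_ensemble([p1, p2], 310.0)
        assert ens.g[0] == pytest.approx(RT310 * np.log(1.5), rel=1e-12)
        assert np.allclose(w[:, 0], [0.75, 0.25])

    def test_bounds_and_weight_normalisation(self):
        rng = np.random.Generator(np.random.Philox(4))
        profiles = [FreeEnergyProfile(GRID, rng.normal(scale=10, size=GRID.shape)) for _ in range(6)]
        ens, w = pr.boltzmann_ensemble(profiles, 310.0)
        gmin = np.min([p.g for p in profiles], axis=0)
        assert np.all(ens.g >= gmin - 1e-9)
        assert np.all(ens.g <= gmin + RT310 * np.log(6) + 1e-9)
        assert np.allclose(w.sum(axis=0), 1.0, atol=1e-12)

    def test_grid_mismatch(self):
        p1 = FreeEnergyProfile(GRID, np.zeros(GRID.shape))
        p2 = FreeEnergyProfile(GRID + 0.5, np.zeros(GRID.shape))
        with pytest.raises(GridMismatch):
            pr.boltzmann_ensemble([p1, p2])


class TestAverage:
    def test_single_profile_identity(self):
        p = FreeEnergyProfile(GRID, np.sin(GRID))
        assert np.allclose(pr.average_profiles([p]).g, p.g)

    def test_mean_and_median(self):
        ps = [profile(v) for v in (0.0, 10.0)]
        assert pr.average_profiles(ps, "mean").g[0] == pytest.approx(5.0)
        assert pr.average_profiles(ps, "median").g[0] == pytest.approx(5.0)
        ps3 = [profile(v) for v in (0.0, 10.0, 100.0)]
        assert pr.average_profiles(ps3, "median").g[0] == pytest.approx(10.0)


class TestBarriers:
    def test_toy_profile_arithmetic(self):
        # water 0, minimum -20 at |z| = 15, core +10
        g = np.zeros(GRID.shape)
        g[np.abs(np.abs(GRID) - 15) < 0.5] = -20.0
        g[np.abs(GRID) < 0.5] = 10.0
        b = pr.extract_barriers(FreeEnergyProfile(GRID, g), smooth_window=1)
        assert b.depth_min == pytest.approx(20.0)
        assert b.barrier_min_to_core == pytest.approx(30.0)
        assert b.barrier_min_to_water == pytest.approx(20.0)
        assert b.dominant_barrier == pytest.approx(30.0)
        assert b.dominant_kind == "to_core"
        assert abs(b.z_min) == pytest.approx(15.0)

    def test_flat_profile_all_zero(self):
        b = pr.extract_barriers(profile(0.0), smooth_window=1)
        assert b.depth_min == 0.0
        assert b.barrier_min_to_core == 0.0
        assert b.barrier_min_to_water == 0.0
        assert b.z_min is None

    def test_offset_invariance_after_normalisation(self):
        rng = np.random.Generator(np.random.Philox(9))
        g = -20 * np.exp(-((np.abs(GRID) - 15) ** 2) / 20)
        a = pr.extract_barriers(pr.normalize_profile(FreeEnergyProfile(GRID, g)))
        b = pr.extract_barriers(pr.normalize_profile(FreeEnergyProfile(GRID, g + 13.0)))
        assert a.depth_min == pytest.approx(b.depth_min)
        assert a.barrier_min_to_core == pytest.approx(b.barrier_min_to_core)

    def test_unnormalised_profile_rejected(self):
        with pytest.raises(NotNormalized):
            pr.extract_barriers(profile(5.0))


class TestOccupancy:
    def test_zero_barrier(self):
        assert pr.occupancy_ratio(0.0) == 1.0

    def test_rt_log10(self):
        assert pr.occupancy_ratio(RT310 * np.log(10), 310.0) == pytest.approx(0.1)

    def test_membrane_center_ionized_bound(self):
        # 53.5 kJ/mol at 310 K: occupancy below 0.001 ppm
        assert pr.occupancy_ratio(53.5, 310.0) < 1e-9


class TestClustering:
    def test_two_obvious_clusters(self):
        a = [profile(0.0) for _ in range(4)]
        b = [profile(50.0) for _ in range(4)]
        labels, _ = pr.cluster_profiles(a + b, 2)
        assert set(labels[:4]) != set(labels[4:])
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1

    def test_order_permutation_invariance(self):
        rng = np.random.Generator(np.random.Philox(6))
        base = [FreeEnergyProfile(GRID, rng.normal(scale=3, size=GRID.shape)) for _ in range(10)]
        labels, _ = pr.cluster_profiles(base, 3)
        perm = rng.permutation(10)
        labels_p, _ = pr.cluster_profiles([base[i] for i in perm], 3)
        # same partition: co-membership matrices agree
        co = lambda lab: np.equal.outer(lab, lab)
        assert np.array_equal(co(labels)[np.ix_(perm, perm)], co(labels_p))


class TestRegression:
    def test_perfect_line(self):
        x = np.arange(10.0)
        slope, intercept, r2 = pr.regress_barrier_vs_affinity(x, 3 * x - 2)
        assert slope == pytest.approx(3.0)
        assert intercept == pytest.approx(-2.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_y(self):
        _, _, r2 = pr.regress_barrier_vs_affinity([1, 2, 3], [5, 5, 5])
        assert r2 == 0.0

    def test_matches_normal_equations(self):
        rng = np.random.Generator(np.random.Philox(8))
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        slope, intercept, r2 = pr.regress_barrier_vs_affinity(x, y)
        X = np.column_stack([x, np.ones(30)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2_ref = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert slope == pytest.approx(beta[0], abs=1e-10)
        assert intercept == pytest.approx(beta[1], abs=1e-10)
        assert r2 == pytest.approx(r2_ref, abs=1e-10)

    def test_constant_x_degenerate(self):
        with pytest.raises(DegenerateInput):
            pr.regress_barrier_vs_affinity([1, 1, 1], [1, 2, 3])


class TestPermeabilityClasses:
    def test_binning_with_boundaries(self):
        vals = [5e-7, 1e-6, 5e-6, 10e-6, 2e-5]
        assert pr.classify_permeability(vals) == [
            "low",
            "moderate",
            "moderate",
            "high",
            "high",
        ]

    def test_invalid_thresholds(self):
        with pytest.raises(InvalidThresholds):
            pr.classify_permeability([1e-6], thresholds=(1e-5, 1e-6))
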