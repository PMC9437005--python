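"""Clearance maps, void classification and occupancy profiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_void_classifier, random_exclusion_grid
from npcvoid.grids import GridSpec, ScalarGrid3D
from npcvoid.mesh import BeadChain, MeshConfiguration
from npcvoid.voids import (VoidGridSpec, classify_voids, compute_rmax,
                           ensemble_average_occupancy, occupancy_profile)


def small_spec(voxel=2.0, n=16):
    half = voxel * n / 2
    return VoidGridSpec.from_bounds((-half,) * 3, (half,) * 3, voxel)


class TestComputeRmax:
    def test_single_bead_distance_minus_radius(self):
        gs = GridSpec((-1, -1, -1), (2, 2, 2), (1, 1, 1))  # center at origin
        spec = VoidGridSpec(gs, 2.0)
        mesh = MeshConfiguration(chains=[BeadChain("a", [[10.0, 0.0, 0.0]])])
        rm = compute_rmax(mesh, (), spec)
        assert rm.values[0, 0, 0] == pytest.approx(7.0)

    def test_empty_world_is_infinite(self):
        spec = small_spec()
        rm = compute_rmax(None, (), spec)
        assert np.all(np.isposinf(rm.values))

    def test_excluded_voxels_carry_negative_sentinel(self):
        spec = small_spec()
        rng = np.random.default_rng(0)
        g = random_exclusion_grid(rng, spec.grid)
        rm = compute_rmax(None, [g], spec)
        excl = g.values > 0
        assert np.all(rm.values[excl] < 0)
        assert np.all(rm.values[~excl] > 0)

    def test_lipschitz_property(self):
        """R_max cannot change faster than the distance between voxel centers."""
        spec = small_spec()
        rng = np.random.default_rng(3)
        beads = rng.uniform(-14, 14, (20, 3))
        mesh = MeshConfiguration(chains=[BeadChain("a", beads)])
        g = random_exclusion_grid(rng, spec.grid)
        r = compute_rmax(mesh, [g], spec).values
        r = np.where(r < 0, 0.0, r)  # sentinel voxels are obstacles: R=0
        for axis, h in zip(range(3), spec.grid.spacing):
            d = np.diff(r, axis=axis)
            assert np.nanmax(np.abs(d)) <= h + 1e-9


class TestClassifyAgainstBruteForce:
    @pytest.mark.parametrize("trial", range(4))
    def test_pipeline_equals_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        spec = small_spec(voxel=2.0, n=16)
        n_beads = int(rng.integers(5, 50))
        beads = rng.uniform(-14, 14, (n_beads, 3))
        mesh = MeshConfiguration(chains=[BeadChain("a", beads)])
        g = random_exclusion_grid(rng, spec.grid, n_blobs=2)
        rm = compute_rmax(mesh, [g], spec)
        for rp in rng.uniform(0.1, 12.0, 5):
            got = classify_voids(rm, rp, spec).accessible
            want = brute_force_void_classifier(beads, g.values > 0, spec.grid,
                                               rp)
            assert np.array_equal(got, want)

    def test_probe_zero_accessible_outside_exclusions(self):
        spec = small_spec()
        rng = np.random.default_rng(1)
        g = random_exclusion_grid(rng, spec.grid)
        rm = compute_rmax(None, [g], spec)
        acc = classify_voids(rm, 0.0, spec).accessible
        assert np.array_equal(acc, ~(g.values > 0))

    def test_negative_radius_rejected(self):
        spec = small_spec()
        rm = compute_rmax(None, (), spec)
        with pytest.raises(ValueError):
            classify_voids(rm, -1.0, spec)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(r1=st.floats(0.0, 10.0), r2=st.floats(0.0, 10.0))
    def test_nested_accessibility(self, r1, r2):
        """Monotonicity: the larger probe's voids are a subset of the smaller's."""
        spec = small_spec()
        rng = np.random.default_rng(8)
        beads = rng.uniform(-14, 14, (25, 3))
        mesh = MeshConfiguration(chains=[BeadChain("a", beads)])
        rm = compute_rmax(mesh, (), spec)
        lo, hi = sorted((r1, r2))
        big = classify_voids(rm, hi, spec).accessible
        small = classify_voids(rm, lo, spec).accessible
        assert np.all(small | ~big)  # big => small

    def test_probe_exclusion_shell_around_chain(self):
        """A 22.4 Å probe is excluded within (22.4 + 3) Å of any bead center."""
        spec = VoidGridSpec.from_bounds((-48, -48, -48), (48, 48, 48), 3.0)
        beads = np.column_stack([np.linspace(-20, 20, 11), np.zeros(11),
                                 np.zeros(11)])
        mesh = MeshConfiguration(chains=[BeadChain("a", beads)])
        rm = compute_rmax(mesh, (), spec)
        acc = classify_voids(rm, 22.4, spec).accessible
        centers = spec.grid.centers()
        from scipy.spatial.distance import cdist

        dmin = cdist(centers, beads).min(axis=1).reshape(acc.shape)
        assert not acc[dmin < 25.4 - 1e-9].any()


class TestOccupancy:
    def test_fully_accessible_unit_fraction(self):
        spec = small_spec()
        rm = compute_rmax(None, (), spec)
        prof = occupancy_profile(classify_voids(rm, 5.0, spec), spec)
        assert np.allclose(prof.P1, 1.0)
        assert np.allclose(prof.A, prof.h * spec.voxel_size**2)

    def test_solid_excluded_slab(self):
        spec = small_spec(voxel=2.0, n=16)
        vals = np.zeros(spec.grid.shape)
        zc = spec.grid.axis_centers(2)
        vals[:, :, np.abs(zc) < 3.0] = 5.0
        g = ScalarGrid3D(spec.grid, vals)
        rm = compute_rmax(None, [g], spec)
        prof = occupancy_profile(classify_voids(rm, 0.0, spec), spec)
        blocked = np.abs(prof.z_centers) < 3.0
        assert np.allclose(prof.P1[blocked], 0.0)
        assert np.allclose(prof.P1[np.abs(prof.z_centers) > 6.0], 1.0)

    def test_recount_oracle(self):
        """h equals a direct per-slab voxel recount on a random map."""
        spec = small_spec()
        rng = np.random.default_rng(12)
        beads = rng.uniform(-14, 14, (30, 3))
        mesh = MeshConfiguration(chains=[BeadChain("a", beads)])
        vm = classify_voids(compute_rmax(mesh, (), spec), 3.0, spec)
        prof = occupancy_profile(vm, spec)
        centers = spec.grid.centers()
        rho = np.hypot(centers[:, 0], centers[:, 1])
        inside = (rho <= spec.profile_radius).reshape(spec.grid.shape)
        zc = spec.grid.axis_centers(2)
        for i, z0 in enumerate(prof.z_centers):
            layer = np.abs(zc - z0) < spec.slab_height / 2
            assert prof.h[i] == (vm.accessible & inside)[:, :, layer].sum()

    def test_cylinder_outside_grid_rejected(self):
        gs = GridSpec((1000.0, 1000.0, 0.0), (2, 2, 2), (4, 4, 4))
        spec = VoidGridSpec(gs, 2.0, profile_radius=5.0)
        vm = classify_voids(compute_rmax(None, (), spec), 0.0, spec)
        with pytest.raises(ValueError):
            occupancy_profile(vm, spec)


class TestEnsembleAverage:
    def _profile(self, h):
        from npcvoid.voids import OccupancyProfile

        n = len(h)
        return OccupancyProfile(
            z_centers=np.arange(n) + 0.5, h=np.asarray(h, float),
            n_total=np.full(n, 100.0), l_c=1.0, A_c=100.0,
        )

    def test_identical_profiles_zero_sem(self):
        p = self._profile([5, 6, 7])
        avg = ensemble_average_occupancy([p, p, p])
        assert np.allclose(avg.h_mean, [5, 6, 7])
        assert np.allclose(avg.h_sem, 0.0)

    def test_two_level_mean(self):
        avg = ensemble_average_occupancy([self._profile([0, 0]),
                                          self._profile([1, 1])])
        assert np.allclose(avg.h_mean, 0.5)

    def test_sem_matches_direct_formula(self):
        rng = np.random.default_rng(7)
        H = rng.integers(0, 50, size=(100, 8)).astype(float)
        profs = [self._profile(h) for h in H]
        avg = ensemble_average_occupancy(profs)
        assert np.allclose(avg.h_sem, H.std(axis=0, ddof=1) / 10.0)
        assert avg.n_frames == 100

    def test_heterogeneous_grids_rejected(self):
        p1 = self._profile([1, 2, 3])
        p2 = self._profile([1, 2])
        with pytest.raises(ValueError):
            ensemble_average_occupancy([p1, p2])
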