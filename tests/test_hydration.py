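"""Cavity counting, fluctuation statistics, residence times, density
profiles and solvation shells, each against an independent oracle."""

import numpy as np
import pytest

from poregate import (
    AtomGroupSpec,
    PoreGeometry,
    SyntheticPoreParams,
    axial_density_profile,
    axial_radial_density_map,
    correlate,
    count_in_cavity,
    hydration_series,
    residence_times,
    shell_counts,
    simulate,
)
from poregate.hydration import series_stats
from poregate.model_core import minimum_image_distance

from conftest import make_frame, water_group


def brute_force_cylinder_count(coords, geo):
    """All-pairs point-in-cylinder oracle using explicit vector algebra."""
    n = 0
    for p in coords:
        rel = p - geo.axis_origin
        z = np.dot(rel, geo.axis_direction)
        r = np.linalg.norm(rel - z * geo.axis_direction)
        if geo.z_lo <= z <= geo.z_hi and r <= geo.radius:
            n += 1
    return n


class TestCountInCavity:
    def test_empty_cylinder(self, axis_geometry):
        frame = make_frame(np.full((10, 3), 8.0))
        assert count_in_cavity(frame, axis_geometry, water_group(10)) == 0

    def test_all_on_axis_mid_cavity(self, axis_geometry):
        coords = np.tile([0.0, 0.0, 1.5], (7, 1))
        frame = make_frame(coords)
        assert count_in_cavity(frame, axis_geometry, water_group(7)) == 7

    def test_matches_brute_force_oracle(self, rng, tilted_geometry):
        coords = rng.uniform(-2, 5, size=(500, 3))
        frame = make_frame(coords)
        got = count_in_cavity(frame, tilted_geometry, water_group(500))
        assert got == brute_force_cylinder_count(coords, tilted_geometry)

    def test_boundary_is_closed(self, axis_geometry):
        geo = axis_geometry
        coords = np.array(
            [
                [geo.radius, 0.0, 0.0],  # r == radius, z == z_lo
                [0.0, 0.0, geo.z_hi],  # z == z_hi
                [geo.radius + 1e-9, 0.0, 1.0],  # just outside radially
            ]
        )
        assert count_in_cavity(make_frame(coords), geo, water_group(3)) == 2

    def test_partition_into_subcylinders_is_exact(self, rng, axis_geometry):
        geo = axis_geometry
        coords = rng.uniform(-1, 4, size=(400, 3))
        frame = make_frame(coords)
        total = count_in_cavity(frame, geo, water_group(400))
        edges = np.linspace(geo.z_lo, geo.z_hi, 7)
        parts = 0
        for lo, hi in zip(edges[:-1], edges[1:]):
            sub = PoreGeometry(
                geo.axis_origin, geo.axis_direction, lo, hi, geo.radius
            )
            parts += count_in_cavity(frame, sub, water_group(400))
        # half-open sub-cylinders: subtract interior boundary double counts
        z, r = np.array([]), np.array([])
        from poregate import to_axis_frame

        z, r = to_axis_frame(frame, geo, np.arange(400))
        doubles = sum(
            int(np.any((np.abs(z - e) < 1e-12) & (r <= geo.radius)))
            for e in edges[1:-1]
        )
        assert parts - doubles == total


class TestHydrationStats:
    def test_constant_series_zero_rsd(self):
        stats = series_stats([5, 5, 5, 5])
        assert stats.sd == 0.0
        assert stats.rsd == 0.0

    def test_hand_formula_oracle(self):
        stats = series_stats([10, 10, 30, 30])
        assert stats.mean == pytest.approx(20.0)
        sd = np.sqrt(((10 - 20) ** 2 * 2 + (30 - 20) ** 2 * 2) / 3)
        assert stats.sd == pytest.approx(sd)
        assert stats.rsd == pytest.approx(sd / 20.0)
        assert stats.sem == pytest.approx(sd / 2.0)

    def test_single_frame_flagged_undefined(self):
        stats = series_stats([4])
        assert not stats.defined
        assert np.isnan(stats.sd)

    def test_telegraph_fluctuations_exceed_constant_rate(self):
        """Two-state wetting modulation inflates the relative SD compared
        to a constant barrier with a similar mean occupancy."""
        wins = 0
        n_seeds = 10
        b = 2.5
        b_eff = -np.log((1 + np.exp(-b)) / 2)  # matches the telegraph mean
        for seed in range(n_seeds):
            common = dict(n_steps=12000, save_stride=40, seed=seed)
            p_tel = SyntheticPoreParams(
                water_barrier=b, wetting_mode="telegraph",
                k_wet=0.01, k_dry=0.01, **common,
            )
            p_const = SyntheticPoreParams(water_barrier=b_eff, **common)
            rsds = []
            for p in (p_tel, p_const):
                traj, _ = simulate(p)
                _, stats = hydration_series(
                    traj, p.geometry(), traj.groups["waters"]
                )
                rsds.append(stats.rsd)
            wins += rsds[0] > rsds[1]
        assert wins >= 8, f"telegraph rsd larger in only {wins}/{n_seeds} seeds"


class TestResidenceTimes:
    @staticmethod
    def frames_from_membership(membership, z_in=1.0, z_out=8.0):
        """Scripted trajectory: particle p is in the cavity at frame f iff
        membership[p][f]."""
        membership = np.asarray(membership, bool)
        n_p, n_f = membership.shape
        frames = []
        for f in range(n_f):
            coords = np.zeros((n_p, 3))
            coords[:, 2] = np.where(membership[:, f], z_in, z_out)
            frames.append(make_frame(coords, time=float(f)))
        return frames

    def test_single_interior_dwell(self, axis_geometry):
        member = np.zeros((1, 10), bool)
        member[0, 3:8] = True  # frames 3..7
        frames = self.frames_from_membership(member)
        dwells = residence_times(frames, axis_geometry, water_group(1), dt=1000.0)
        assert len(dwells) == 1
        assert dwells[0].duration == pytest.approx(5.0)  # ns
        assert not dwells[0].censored

    def test_never_inside(self, axis_geometry):
        frames = self.frames_from_membership(np.zeros((2, 5), bool))
        assert residence_times(frames, axis_geometry, water_group(2), dt=1.0) == []

    def test_edge_runs_censored(self, axis_geometry):
        member = np.zeros((1, 6), bool)
        member[0, :2] = True
        member[0, 4:] = True
        frames = self.frames_from_membership(member)
        dwells = residence_times(frames, axis_geometry, water_group(1), dt=1.0)
        assert [d.censored for d in dwells] == [True, True]

    def test_matches_run_length_encoding_oracle(self, rng, axis_geometry):
        member = rng.random((6, 40)) < 0.4
        frames = self.frames_from_membership(member)
        dwells = residence_times(frames, axis_geometry, water_group(6), dt=1.0)
        got = sorted(round(d.duration * 1000) for d in dwells)
        expected = []
        for row in member:
            run = 0
            for val in row:
                if val:
                    run += 1
                elif run:
                    expected.append(run)
                    run = 0
            if run:
                expected.append(run)
        assert got == sorted(expected)

    def test_gap_tolerance_merges_single_excursions(self, axis_geometry):
        member = np.zeros((1, 9), bool)
        member[0, 1:4] = True
        member[0, 5:8] = True  # one-frame gap at 4
        frames = self.frames_from_membership(member)
        strict = residence_times(frames, axis_geometry, water_group(1), dt=1.0)
        merged = residence_times(
            frames, axis_geometry, water_group(1), dt=1.0, gap_tolerance=1
        )
        assert len(strict) == 2
        assert len(merged) == 1


class TestDensityProfiles:
    def make_ideal_gas_frames(self, rng, n, n_frames, box=(4.0, 4.0, 8.0)):
        return [
            make_frame(rng.uniform(0, 1, (n, 3)) * np.asarray(box), box=box)
            for _ in range(n_frames)
        ]

    def test_uniform_gas_flat_profile_within_poisson(self, rng):
        geo = PoreGeometry([2, 2, 0], [0, 0, 1], 2.0, 6.0, 1.0)
        n, n_frames = 500, 200
        frames = self.make_ideal_gas_frames(rng, n, n_frames)
        group = water_group(n)
        prof = axial_density_profile(
            frames, geo, group, bin_width=0.5, bulk_slab=(0.5, 1.5)
        )
        rho0 = n / (4.0 * 4.0 * 8.0)
        bin_vol = np.pi * 1.0**2 * 0.5
        for dens, cnt in zip(prof.density, prof.counts):
            sigma = np.sqrt(max(cnt, 1.0)) / (n_frames * bin_vol)
            assert abs(dens - rho0) < 3.5 * sigma
        assert prof.bulk_density == pytest.approx(rho0, rel=0.15)

    def test_zero_particles_all_zero(self, axis_geometry):
        frames = [make_frame(np.full((5, 3), 9.0)) for _ in range(3)]
        prof = axial_density_profile(frames, axis_geometry, water_group(5))
        assert np.all(prof.density == 0)

    def test_frame_duplication_leaves_density_unchanged(self, rng, axis_geometry):
        frames = [make_frame(rng.uniform(0, 3, (50, 3)))]
        p1 = axial_density_profile(frames, axis_geometry, water_group(50))
        p2 = axial_density_profile(frames * 4, axis_geometry, water_group(50))
        assert np.allclose(p1.density, p2.density)

    def test_profile_integrates_to_mean_cavity_count(self, rng, axis_geometry):
        frames = [make_frame(rng.uniform(-1, 4, (200, 3))) for _ in range(5)]
        group = water_group(200)
        prof = axial_density_profile(frames, axis_geometry, group, bin_width=0.25)
        bin_vol = np.pi * axis_geometry.radius**2 * 0.25
        integral = np.sum(prof.density) * bin_vol
        mean_count = np.mean(
            [count_in_cavity(f, axis_geometry, group) for f in frames]
        )
        # binning uses half-open bins; counts on the exact upper boundary
        # may differ, but for continuous random coordinates they agree
        assert integral == pytest.approx(mean_count, rel=1e-9)

    def test_map_marginalises_to_axial_profile(self, rng, axis_geometry):
        frames = [make_frame(rng.uniform(-1, 4, (300, 3))) for _ in range(4)]
        group = water_group(300)
        prof = axial_density_profile(frames, axis_geometry, group, bin_width=0.5)
        z_c, r_c, dmap = axial_radial_density_map(
            frames, axis_geometry, group, dz=0.5, dr=0.2
        )
        r_edges = 0.2 * np.arange(len(r_c) + 1)
        shell_vol = np.pi * (r_edges[1:] ** 2 - r_edges[:-1] ** 2) * 0.5
        axial_from_map = (dmap * shell_vol[None, :]).sum(axis=1) / (
            np.pi * axis_geometry.radius**2 * 0.5
        )
        assert np.allclose(axial_from_map, prof.density, rtol=1e-9)

    def test_confined_particles_leave_outer_bins_empty(self, rng, axis_geometry):
        xy = rng.uniform(-0.1, 0.1, (100, 2))
        z = rng.uniform(0, 3, 100)
        frames = [make_frame(np.column_stack([xy, z]))]
        _, r_c, dmap = axial_radial_density_map(
            frames, axis_geometry, water_group(100), dz=0.5, dr=0.2
        )
        assert np.all(dmap[:, r_c > 0.2] == 0)

    def test_overlapping_bulk_slab_rejected(self, axis_geometry):
        frames = [make_frame(np.zeros((1, 3)))]
        with pytest.raises(ValueError):
            axial_density_profile(
                frames, axis_geometry, water_group(1), bulk_slab=(2.5, 3.5)
            )


class TestShellCounts:
    def test_no_waters(self, axis_geometry):
        frame = make_frame(np.zeros((1, 3)))
        sc = shell_counts(frame, 0, AtomGroupSpec("w", [], "water_oxygen"))
        assert (sc.n_first, sc.n_two_shell) == (0, 0)

    def test_constructed_shells(self):
        ion = np.zeros(3)
        dirs = np.eye(3)
        first = np.vstack([0.28 * dirs, -0.28 * dirs])  # 6 at 0.28 nm
        second = np.vstack([0.5 * dirs, -0.5 * dirs, [[0.5 / np.sqrt(2), 0.5 / np.sqrt(2), 0]] * 4])
        coords = np.vstack([[ion], first, second])
        frame = make_frame(coords, box=(20, 20, 20))
        waters = AtomGroupSpec("w", np.arange(1, len(coords)), "water_oxygen")
        sc = shell_counts(frame, 0, waters, r1=0.36, r2=0.61)
        assert sc.n_first == 6
        assert sc.n_two_shell == 16

    def test_minimum_image_applied(self):
        coords = np.array([[0.1, 0, 0], [9.9, 0, 0]])  # 0.2 nm via the image
        frame = make_frame(coords, box=(10, 10, 10))
        waters = AtomGroupSpec("w", [1], "water_oxygen")
        sc = shell_counts(frame, 0, waters, r1=0.36, r2=0.61)
        assert sc.n_first == 1

    def test_matches_all_pairs_oracle(self, rng):
        box = np.array([3.0, 3.0, 3.0])
        coords = rng.uniform(0, 3, (80, 3))
        frame = make_frame(coords, box=box)
        waters = AtomGroupSpec("w", np.arange(1, 80), "water_oxygen")
        sc = shell_counts(frame, 0, waters, r1=0.36, r2=0.61)
        n1 = n2 = 0
        for w in coords[1:]:
            d = w - coords[0]
            d -= box * np.round(d / box)
            dist = np.sqrt(np.sum(d * d))
            n1 += dist <= 0.36
            n2 += dist <= 0.61
        assert (sc.n_first, sc.n_two_shell) == (n1, n2)

    def test_bad_cutoffs_rejected(self):
        frame = make_frame(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            shell_counts(frame, 0, AtomGroupSpec("w", [1], "water_oxygen"), 0.6, 0.3)


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(5.0)
        assert correlate(x, 2 * x + 1) == pytest.approx(1.0)

    def test_anticorrelated(self):
        x = np.arange(5.0)
        assert correlate(x, -x) == pytest.approx(-1.0)

    def test_hand_formula_five_points(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 9.0])
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert correlate(x, y) == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_undefined(self):
        assert correlate([1, 1, 1], [1, 2, 3]) is None

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            correlate([1, 2], [3, 4])
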