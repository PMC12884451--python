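"""Exclusive water assignment, coordination curves, density maps, shifts."""
import numpy as np
import pytest

from quadhop import synthetic as syn
from quadhop.core import SITE_ORDER, Frame
from quadhop.hydration import (
    DensityGrid,
    assign_waters_exclusive,
    coordination_change,
    coordination_curve,
    density_map,
    difference_map,
    make_grid,
    measure_shift,
    rdf,
)


@pytest.fixture(scope="module")
def quad_sites(reference_sites):
    return reference_sites


def frame_with_waters(sites, waters, state="124A+"):
    return Frame(0, 0.0, state, sites, waters=np.asarray(waters, float))


class TestExclusiveAssignment:
    def test_obvious_nearest_site(self, quad_sites):
        nh = quad_sites["124A"].nh_position
        out = nh - np.mean([quad_sites[s].coords.mean(0) for s in SITE_ORDER], axis=0)
        out /= np.linalg.norm(out)
        frame = frame_with_waters(quad_sites, [nh + 2.5 * out])
        [(site, d)] = assign_waters_exclusive(frame)
        assert site == "124A"
        assert d <= 2.5 + 1e-9

    def test_equidistant_tie_goes_to_fixed_order(self, quad_sites):
        nh_a = quad_sites["124A"].nh_position
        nh_b = quad_sites["122A"].nh_position
        mid = 0.5 * (nh_a + nh_b)
        frame = frame_with_waters(quad_sites, [mid])
        [(site, _)] = assign_waters_exclusive(frame, mode="nh")
        assert site == "124A"  # first of the tied sites in fixed order

    def test_matches_brute_force_oracle(self, quad_sites, rng):
        centroid = np.mean([quad_sites[s].coords.mean(0) for s in SITE_ORDER], axis=0)
        waters = centroid + rng.uniform(-6, 6, size=(50, 3))
        frame = frame_with_waters(quad_sites, waters)
        got = assign_waters_exclusive(frame)
        for w, (site, d) in zip(waters, got):
            dists = {
                s: min(np.linalg.norm(w - a) for a in quad_sites[s].coords)
                for s in SITE_ORDER
            }
            best = min(dists.values())
            assert d == pytest.approx(best, abs=1e-9)
            assert dists[site] == pytest.approx(best, abs=1e-9)

    def test_partition_property(self, quad_sites, rng):
        """Per-frame sums of per-site counts at any cutoff equal the number
        of waters within that cutoff of at least one site, counted once."""
        centroid = np.mean([quad_sites[s].coords.mean(0) for s in SITE_ORDER], axis=0)
        waters = centroid + rng.uniform(-6, 6, size=(80, 3))
        frame = frame_with_waters(quad_sites, waters)
        assigned = assign_waters_exclusive(frame)
        for r in (2.0, 3.5, 5.0):
            per_site_total = sum(1 for _, d in assigned if d <= r)
            within_any = sum(
                1
                for w in waters
                if min(
                    min(np.linalg.norm(w - a) for a in quad_sites[s].coords)
                    for s in SITE_ORDER
                )
                <= r
            )
            assert per_site_total == within_any


class TestCoordinationCurve:
    def test_single_water_step_function(self, quad_sites):
        nh = quad_sites["124A"].nh_position
        centroid = np.mean([quad_sites[s].coords.mean(0) for s in SITE_ORDER], axis=0)
        out = (nh - centroid) / np.linalg.norm(nh - centroid)
        frame = frame_with_waters(quad_sites, [nh + 2.5 * out])
        curve = coordination_curve([frame], "124A", [2.0, 2.4, 2.6, 3.0], mode="nh")
        assert list(curve.n_water) == [0.0, 0.0, 1.0, 1.0]

    def test_monotone_in_cutoff(self, shift_trajectory):
        frames = shift_trajectory.select_state("124A+")[:50]
        for site in SITE_ORDER:
            curve = coordination_curve(frames, site, np.arange(2.0, 6.0, 0.5))
            assert (np.diff(curve.n_water) >= -1e-12).all()

    def test_switch_changes_coordination_signs(self, shift_trajectory):
        """After the forced 124A+ -> 122D+ transfer the planted bridging-water
        shift raises 122D coordination and lowers 124A coordination."""
        fi = shift_trajectory.select_state("124A+")
        ff = shift_trajectory.select_state("122D+")
        ch = coordination_change(fi, ff, [3.0, 3.5], mode="nh")
        assert (ch["122D"].n_water > 0).all()
        assert (ch["124A"].n_water < 0).all()

    def test_empty_cutoffs_rejected(self, shift_trajectory):
        with pytest.raises(ValueError, match="cutoff"):
            coordination_curve(shift_trajectory.frames[:2], "124A", [])


class TestDensityMap:
    def test_frozen_water_conserves_integral(self, quad_sites):
        nh = quad_sites["124A"].nh_position
        frames = [frame_with_waters(quad_sites, [nh + np.array([1.5, 0, 0])])] * 20
        grid = density_map(frames, bandwidth=0.3)
        assert grid.integral() == pytest.approx(1.0, abs=0.01)

    def test_uniform_waters_reach_bulk_density(self, quad_sites, rng):
        """Uniformly random waters at bulk number density produce a masked
        mean density close to rho0 (Monte-Carlo check)."""
        grid0 = make_grid(
            {s: quad_sites[s].nh_position for s in SITE_ORDER}, spacing=0.25
        )
        lo = grid0.origin
        hi = grid0.origin + grid0.spacing * np.array(grid0.shape)
        vol = np.prod(hi - lo)
        rho0 = grid0.rho0
        n_per_frame = int(round(rho0 * vol))
        frames = [
            frame_with_waters(quad_sites, rng.uniform(lo, hi, size=(n_per_frame, 3)))
            for _ in range(60)
        ]
        grid = density_map(frames, grid=grid0, bandwidth=0.0, superpose=False)
        assert grid.masked_mean() == pytest.approx(rho0, rel=0.1)

    def test_rigid_transform_invariance(self, shift_trajectory, rng):
        frames = shift_trajectory.select_state("124A+")[:30]
        grid = make_grid(frames[0].nh_positions())
        rho = density_map(frames, grid=grid)
        theta = 0.4
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        t = np.array([3.0, -1.0, 2.0])
        moved = []
        for f in frames[1:]:  # keep the first frame as the common reference
            sites = {k: s.transformed(R, t) for k, s in f.sites.items()}
            moved.append(
                Frame(f.frame_index, f.time, f.state, sites, waters=f.waters @ R.T + t)
            )
        rho2 = density_map([frames[0]] + moved, grid=grid)
        assert np.allclose(rho.values, rho2.values, atol=1e-6)

    def test_identical_inputs_give_zero_difference(self, shift_trajectory):
        frames = shift_trajectory.select_state("124A+")[:30]
        grid = make_grid(frames[0].nh_positions())
        r1 = density_map(frames, grid=grid)
        r2 = density_map(frames, grid=grid)
        result = difference_map(r2, r1)
        assert np.allclose(result.grid.values, 0.0)
        assert result.regions == []


class TestDifferenceMap:
    def test_incongruent_grids_rejected(self, quad_sites):
        g1 = make_grid({s: quad_sites[s].nh_position for s in SITE_ORDER}, spacing=0.2)
        g2 = make_grid({s: quad_sites[s].nh_position for s in SITE_ORDER}, spacing=0.25)
        d1 = DensityGrid(g1.origin, g1.spacing, g1.shape, np.zeros(g1.shape))
        d2 = DensityGrid(g2.origin, g2.spacing, g2.shape, np.zeros(g2.shape))
        with pytest.raises(ValueError, match="congruent"):
            difference_map(d1, d2)

    def test_antisymmetry(self, shift_trajectory):
        fi = shift_trajectory.select_state("124A+")[:100]
        ff = shift_trajectory.select_state("122D+")[:100]
        grid = make_grid(fi[0].nh_positions())
        ri = density_map(fi, grid=grid)
        rf = density_map(ff, grid=grid)
        fwd = difference_map(rf, ri)
        bwd = difference_map(ri, rf)
        assert np.allclose(fwd.grid.values, -bwd.grid.values, atol=1e-12)

    def test_integral_linearity(self, shift_trajectory):
        fi = shift_trajectory.select_state("124A+")[:50]
        ff = shift_trajectory.select_state("122D+")[:50]
        grid = make_grid(fi[0].nh_positions())
        ri = density_map(fi, grid=grid)
        rf = density_map(ff, grid=grid)
        diff = difference_map(rf, ri)
        assert diff.grid.integral() == pytest.approx(rf.integral() - ri.integral(), abs=1e-9)

    def test_planted_shift_produces_one_dipole_pair(self, shift_trajectory):
        """The planted bridging-water shift shows up as exactly one positive
        region (toward the newly oxidized 122D NH) and one negative region
        (toward the 124A NH it left)."""
        fi = shift_trajectory.select_state("124A+")
        ff = shift_trajectory.select_state("122D+")
        grid = make_grid(fi[0].nh_positions())
        ri = density_map(fi, grid=grid)
        rf = density_map(ff, grid=grid)
        result = difference_map(rf, ri)
        assert len(result.positive_regions) == 1
        assert len(result.negative_regions) == 1
        nh_dst = fi[0].sites["122D"].nh_position
        nh_src = fi[0].sites["124A"].nh_position
        pos, neg = result.positive_regions[0], result.negative_regions[0]
        assert np.linalg.norm(pos.centroid - nh_dst) < np.linalg.norm(pos.centroid - nh_src)
        assert np.linalg.norm(neg.centroid - nh_src) < np.linalg.norm(neg.centroid - nh_dst)

    def test_null_shift_produces_no_regions(self, reference_structure):
        hyd = syn.HydrationSpec(shift_magnitude=0.0, jitter_sigma=0.05, seed=21)
        traj = syn.gen_trajectory(reference_structure, hyd, 300, "122D+")
        fi, ff = traj.select_state("124A+"), traj.select_state("122D+")
        grid = make_grid(fi[0].nh_positions())
        result = difference_map(density_map(ff, grid=grid), density_map(fi, grid=grid))
        assert result.regions == []


class TestMeasureShift:
    @pytest.mark.parametrize("planted", [0.05, 0.15, 0.3])
    def test_recovery_across_planted_range(self, reference_structure, planted):
        hyd = syn.HydrationSpec(shift_magnitude=planted, jitter_sigma=0.05,
                                seed=int(planted * 100))
        traj = syn.gen_trajectory(reference_structure, hyd, 500, "122D+")
        got = measure_shift(
            traj.select_state("124A+"), traj.select_state("122D+"), "122D"
        )
        assert got == pytest.approx(planted, abs=0.02)

    def test_antisymmetry_under_mirrored_input(self, shift_trajectory):
        fi = shift_trajectory.select_state("124A+")
        ff = shift_trajectory.select_state("122D+")
        fwd = measure_shift(fi, ff, "122D")
        bwd = measure_shift(ff, fi, "122D")
        assert bwd == pytest.approx(-fwd, abs=0.01)

    def test_no_nearby_water_rejected(self, quad_sites):
        far = quad_sites["124A"].nh_position + np.array([50.0, 0, 0])
        frames = [frame_with_waters(quad_sites, [far])] * 5
        with pytest.raises(ValueError, match="no water"):
            measure_shift(frames, frames, "124A")

    def test_grid_based_estimate_agrees_in_sign_and_scale(self, shift_trajectory):
        fi = shift_trajectory.select_state("124A+")
        ff = shift_trajectory.select_state("122D+")
        grid = make_grid(fi[0].nh_positions())
        ri = density_map(fi, grid=grid)
        rf = density_map(ff, grid=grid)
        got = measure_shift(ri, rf, fi[0].sites["122D"].nh_position)
        # the KDE-smoothed grid estimator is biased low by window truncation
        # but must agree in sign and order of magnitude
        assert 0.05 < got < 0.2


class TestRdf:
    def test_bulk_water_gr_near_unity(self, quad_sites, rng):
        grid0 = make_grid({s: quad_sites[s].nh_position for s in SITE_ORDER}, spacing=0.5,
                          pad=4.0)
        lo = grid0.origin
        hi = grid0.origin + grid0.spacing * np.array(grid0.shape)
        n = int(round(grid0.rho0 * np.prod(hi - lo)))
        frames = [
            frame_with_waters(quad_sites, rng.uniform(lo, hi, size=(n, 3)))
            for _ in range(40)
        ]
        r, g = rdf(frames, "124A", r_max=5.0, dr=0.5)
        assert g[(r > 2.0) & (r < 5.0)].mean() == pytest.approx(1.0, rel=0.15)
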