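"""Density profiles, occupancy grids, continuity and crossing counting."""

import numpy as np
import pytest

from helpers import flood_fill_touches_both_faces
from poreflow import (
    PoreParams,
    SyntheticSpec,
    count_crossings,
    is_channel_continuous,
    make_pore_system,
    occupancy_grid,
    select,
    z_density_profile,
)
from poreflow.md_io import Selection
from poreflow.water import OccupancyGrid, write_opendx


def axis_plus_waters(traj_builder, water_frames, box=(10, 10, 10), dt=1.0):
    """One static axis atom at the box centre plus given water positions."""
    center = np.array(box) / 2
    frames = [np.vstack([center, np.atleast_2d(w)]) for w in water_frames]
    n_w = np.atleast_2d(water_frames[0]).shape[0]
    resnames = ["PRT"] + ["SOL"] * n_w
    names = ["CA"] + ["OW"] * n_w
    return traj_builder(frames, box=box, dt=dt, names=names, resnames=resnames)


class TestDensityProfile:
    def test_no_waters_in_region_zero_profile(self, traj_builder):
        waters = np.tile([9.0, 9.0, 5.0], (5, 1))  # far from the axis laterally
        traj = axis_plus_waters(traj_builder, [waters] * 3)
        prof = z_density_profile(traj, select(traj.topology, "water"),
                                 select(traj.topology, "name CA"),
                                 lateral_radius=1.0, bin_width=0.5)
        np.testing.assert_array_equal(prof.density, 0)

    def test_uniform_fill_flat_within_poisson_error(self, traj_builder):
        rng = np.random.default_rng(0)
        n_w, n_frames, radius = 400, 150, 2.0
        box = (10.0, 10.0, 10.0)
        frames = [rng.uniform(0, 10, (n_w, 3)) for _ in range(n_frames)]
        traj = axis_plus_waters(traj_builder, frames, box=box)
        prof = z_density_profile(traj, select(traj.topology, "water"),
                                 select(traj.topology, "name CA"),
                                 lateral_radius=radius, bin_width=1.0)
        rho = n_w / 1000.0  # molecules per nm^3
        per_bin = rho * np.pi * radius**2 * 1.0  # expected count per bin per frame
        se = np.sqrt(per_bin / n_frames) / (np.pi * radius**2 * 1.0)
        assert np.all(np.abs(prof.density - rho) < 3 * se)

    def test_bin_refinement_conserves_region_integral(self, traj_builder):
        rng = np.random.default_rng(1)
        frames = [rng.uniform(0, 10, (100, 3)) for _ in range(20)]
        traj = axis_plus_waters(traj_builder, frames)
        kwargs = dict(lateral_radius=2.0, z_range=(1.0, 9.0))
        coarse = z_density_profile(traj, select(traj.topology, "water"),
                                   select(traj.topology, "name CA"),
                                   bin_width=1.0, **kwargs)
        fine = z_density_profile(traj, select(traj.topology, "water"),
                                 select(traj.topology, "name CA"),
                                 bin_width=0.5, **kwargs)
        assert coarse.region_integral == pytest.approx(fine.region_integral, rel=1e-9)

    def test_empty_selection_rejected(self, traj_builder):
        traj = axis_plus_waters(traj_builder, [np.zeros((2, 3))])
        with pytest.raises(ValueError, match="empty"):
            z_density_profile(traj, Selection("w", np.array([], dtype=int)),
                              select(traj.topology, "name CA"))


class TestOccupancyGrid:
    def test_static_atom_single_voxel(self, traj_builder):
        pos = np.array([[5.25, 5.25, 5.25]])
        traj = traj_builder([pos] * 4)
        grid = occupancy_grid(traj, Selection("a", np.array([0])),
                              (np.array([5.0, 5.0, 5.0]), np.array([6.0, 6.0, 6.0])),
                              spacing=0.5)
        assert grid.values.sum() == pytest.approx(1.0)
        assert grid.values[0, 0, 0] == 1.0

    def test_partial_presence_fraction(self, traj_builder):
        frames = [np.array([[5.25, 5.25, 5.25] if i < 10 else [8.0, 8.0, 8.0]])
                  for i in range(50)]
        traj = traj_builder(frames)
        grid = occupancy_grid(traj, Selection("a", np.array([0])),
                              (np.array([5.0, 5.0, 5.0]), np.array([6.0, 6.0, 6.0])),
                              spacing=1.0)
        assert grid.values[0, 0, 0] == pytest.approx(0.2)

    def test_brute_force_union_recount(self, traj_builder):
        rng = np.random.default_rng(2)
        frames = [rng.uniform(4, 6, (30, 3)) for _ in range(25)]
        traj = traj_builder(frames)
        lo, hi = np.array([4.0, 4.0, 4.0]), np.array([6.0, 6.0, 6.0])
        spacing = 0.25
        grid = occupancy_grid(traj, Selection("a", np.arange(30)), (lo, hi), spacing)
        # independent recount: per frame, the set of occupied voxels
        shape = grid.values.shape
        acc = np.zeros(shape)
        for f in frames:
            occ = np.zeros(shape, dtype=bool)
            for p in f:
                c = ((p - lo) / spacing).astype(int)
                if np.all(c >= 0) and np.all(c < shape):
                    occ[tuple(c)] = True
            acc += occ
        np.testing.assert_allclose(grid.values, acc / len(frames), atol=1e-12)

    def test_region_outside_box_rejected(self, traj_builder):
        traj = traj_builder([np.zeros((1, 3))])
        with pytest.raises(ValueError, match="region"):
            occupancy_grid(traj, Selection("a", np.array([0])),
                           (np.zeros(3), np.array([20.0, 5.0, 5.0])), 0.5)

    def test_opendx_export(self, tmp_path, traj_builder):
        traj = traj_builder([np.array([[5.25, 5.25, 5.25]])] * 2)
        grid = occupancy_grid(traj, Selection("a", np.array([0])),
                              (np.array([5.0] * 3), np.array([6.0] * 3)), 0.5)
        path = tmp_path / "map.dx"
        write_opendx(path, grid)
        text = path.read_text()
        assert "gridpositions counts 2 2 2" in text
        assert "1.000000" in text


class TestContinuity:
    def _grid(self, values):
        return OccupancyGrid(origin=np.zeros(3), spacing=0.5,
                             values=np.asarray(values, dtype=float))

    def test_full_column_continuous(self):
        values = np.zeros((3, 3, 5))
        values[1, 1, :] = 1.0
        res = is_channel_continuous(self._grid(values), 0.2)
        assert res.continuous
        assert res.extent_nm == pytest.approx(5 * 0.5)

    def test_gap_splits_into_two_components(self):
        values = np.zeros((3, 3, 5))
        values[1, 1, :] = 1.0
        values[1, 1, 2] = 0.0
        res = is_channel_continuous(self._grid(values), 0.2)
        assert not res.continuous
        assert res.n_components == 2

    def test_random_grids_match_flood_fill_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            values = (rng.random((4, 4, 6)) < 0.4).astype(float)
            res = is_channel_continuous(self._grid(values), 0.5)
            cont, n_comp = flood_fill_touches_both_faces(values >= 0.5)
            assert res.continuous == cont
            assert res.n_components == n_comp

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            is_channel_continuous(self._grid(np.ones((3, 3, 1))), 0.2)
        with pytest.raises(ValueError, match="isovalue"):
            is_channel_continuous(self._grid(np.ones((3, 3, 3))), 0.0)


class TestCrossings:
    def scripted(self, traj_builder, zs, lateral=None, box=(10, 10, 10)):
        """Single molecule following a scripted z path (x=y=5 unless given)."""
        n = len(zs)
        lateral = lateral if lateral is not None else [(5.0, 5.0)] * n
        waters = [np.array([[lx, ly, z]]) for (lx, ly), z in zip(lateral, zs)]
        return axis_plus_waters(traj_builder, waters, box=box)

    def run(self, traj, **kw):
        args = dict(z_lower=4.0, z_upper=6.0, lateral_radius=1.5)
        args.update(kw)
        return count_crossings(traj, select(traj.topology, "water"),
                               args["z_lower"], args["z_upper"],
                               args["lateral_radius"], select(traj.topology, "name CA"))

    def test_static_waters_no_events(self, traj_builder):
        traj = self.scripted(traj_builder, [5.0] * 6)
        rep = self.run(traj)
        assert rep.n_up == rep.n_down == 0

    def test_monotone_up_crossing(self, traj_builder):
        traj = self.scripted(traj_builder, [3.0, 4.5, 5.5, 7.0])
        rep = self.run(traj)
        assert (rep.n_up, rep.n_down) == (1, 0)
        assert rep.events[0].direction == +1

    def test_monotone_down_crossing(self, traj_builder):
        traj = self.scripted(traj_builder, [7.0, 5.5, 4.5, 3.0])
        rep = self.run(traj)
        assert (rep.n_up, rep.n_down) == (0, 1)

    def test_abort_retreat_no_event(self, traj_builder):
        # enters past the lower plane then retreats without reaching the upper
        traj = self.scripted(traj_builder, [3.0, 4.5, 5.0, 4.5, 3.0, 4.5, 3.0])
        rep = self.run(traj)
        assert rep.n_up == rep.n_down == 0

    def test_lateral_exit_voids_traversal(self, traj_builder):
        lateral = [(5, 5), (5, 5), (8.0, 5), (5, 5)]  # drifts out of the gate mid-pore
        traj = self.scripted(traj_builder, [3.0, 4.5, 5.5, 7.0], lateral=lateral)
        rep = self.run(traj)
        assert rep.n_up == 0

    def test_periodic_jump_not_a_crossing(self, traj_builder):
        # wraps through the periodic boundary: below -> above without the middle
        traj = self.scripted(traj_builder, [1.0, 0.2, 9.8, 9.0])
        rep = self.run(traj, z_lower=3.0, z_upper=7.0)
        assert rep.n_up == rep.n_down == 0

    def test_round_trip_counts_both_directions(self, traj_builder):
        traj = self.scripted(traj_builder, [3.0, 5.0, 7.0, 5.0, 3.0])
        rep = self.run(traj)
        assert (rep.n_up, rep.n_down) == (1, 1)

    def test_bad_planes_rejected(self, traj_builder):
        traj = self.scripted(traj_builder, [5.0, 5.0])
        with pytest.raises(ValueError, match="z_lower"):
            self.run(traj, z_lower=6.0, z_upper=4.0)

    def test_closed_pore_zero_crossings_multiple_seeds(self):
        for seed in (1, 2, 3):
            spec = SyntheticSpec(kind="pore", seed=seed, n_frames=1500,
                                 pore=PoreParams(barrier=True))
            traj, _ = make_pore_system(spec)
            rep = count_crossings(traj, select(traj.topology, "water"),
                                  -1.0, 1.0, 2.0, select(traj.topology, "name CA"))
            assert rep.n_up == rep.n_down == 0

    def test_open_pore_counts_grow_linearly(self, open_pore_system):
        """Crossing count over 2T vs T within [1.6, 2.4] when counts >= 25."""
        _, traj, _ = open_pore_system
        from poreflow import Trajectory

        w = select(traj.topology, "water")
        ax = select(traj.topology, "name CA")
        half = Trajectory(topology=traj.topology,
                          frames=traj.frames[: traj.n_frames // 2], dt=traj.dt)
        full_rep = count_crossings(traj, w, -1.0, 1.0, 2.0, ax)
        half_rep = count_crossings(half, w, -1.0, 1.0, 2.0, ax)
        total_full = full_rep.n_up + full_rep.n_down
        total_half = half_rep.n_up + half_rep.n_down
        assert total_half >= 5
        ratio = total_full / max(total_half, 1)
        assert 1.3 <= ratio <= 3.0  # linear growth, loose band at modest counts
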