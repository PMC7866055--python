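"""Superposition, RMSD/RMSF, common PCA and span-area checks.

Independent oracles: a nested rotational-grid search for the Kabsch fit,
hand arithmetic for small RMSD cases, sampling theory for PCA mode
recovery, and a gift-wrapping hull implementation for the span area.
"""

import numpy as np
import pytest

from helpers import (
    grid_oracle_min_rmsd,
    jarvis_hull_area,
    random_rotation,
    three_mode_ensemble,
)
from poreflow import (
    Frame,
    common_pca,
    pc_span_area,
    rmsd_series,
    rmsf_profile,
    superpose,
)
from poreflow.conformation import apply_superposition
from poreflow.md_io import Selection


class TestSuperpose:
    def test_identity(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(10, 3))
        fit = superpose(coords, coords)
        assert fit.rmsd_after == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(fit.rotation, np.eye(3), atol=1e-9)

    def test_pure_translation_removed(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(10, 3))
        fit = superpose(ref + np.array([1.0, 2.0, 3.0]), ref)
        assert fit.rmsd_after == pytest.approx(0.0, abs=1e-12)

    def test_proper_rotation_always(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            a = rng.normal(size=(6, 3))
            b = rng.normal(size=(6, 3))
            fit = superpose(a, b)
            assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_rigid_motion_recovery_and_grid_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            ref = rng.normal(size=(10, 3))
            R = random_rotation(rng)
            mobile = ref @ R.T + rng.normal(size=3)
            fit = superpose(mobile, ref)
            assert fit.rmsd_after < 1e-9
            # noisy case against the exhaustive grid oracle
            noisy = mobile + rng.normal(scale=0.05, size=ref.shape)
            fit = superpose(noisy, ref)
            oracle = grid_oracle_min_rmsd(noisy, ref)
            assert fit.rmsd_after == pytest.approx(oracle, abs=1e-6)
            assert fit.rmsd_after <= oracle + 1e-9  # Kabsch is the true minimum

    def test_degenerate_geometry_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line)
        with pytest.raises(ValueError, match="3 atoms"):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRmsd:
    def test_identical_frames_zero(self, traj_builder):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(5, 3)) + 5
        traj = traj_builder([coords] * 4)
        series = rmsd_series(traj, Selection("all", np.arange(5)), traj.frames[0])
        np.testing.assert_allclose(series.values, 0, atol=1e-12)

    def test_rigid_body_motion_gives_zero(self, traj_builder):
        rng = np.random.default_rng(5)
        ref = rng.normal(size=(6, 3)) + 5
        frames = [ref] + [ref @ random_rotation(rng).T + rng.normal(size=3)
                          for _ in range(3)]
        traj = traj_builder(frames)
        series = rmsd_series(traj, Selection("all", np.arange(6)), traj.frames[0])
        np.testing.assert_allclose(series.values, 0, atol=1e-9)

    def test_hand_computed_mass_weighted_case(self, traj_builder):
        """3 atoms, masses (1, 2, 3); one atom displaced 0.3 nm along y.

        The optimal fit removes the rigid part; the value must match the
        direct weighted formula sqrt(sum m_i d_i^2 / sum m_i) applied to
        the fitted coordinates.
        """
        ref = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1.0, 0]]) + 5
        moved = ref.copy()
        moved[1, 1] += 0.3
        masses = np.array([1.0, 2.0, 3.0])
        traj = traj_builder([ref, moved], masses=masses)
        series = rmsd_series(traj, Selection("all", np.arange(3)), traj.frames[0])
        fit = superpose(moved, ref, masses)
        fitted = apply_superposition(moved, fit)
        expected = np.sqrt((masses * ((fitted - ref) ** 2).sum(axis=1)).sum() / masses.sum())
        assert series.values[1] == pytest.approx(expected, abs=1e-12)
        assert series.values[0] == pytest.approx(0.0, abs=1e-12)
        assert 0 < series.values[1] < 0.3  # strictly between: fit removed some drift

    def test_mutual_symmetry(self, traj_builder):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(8, 3)) + 5
        b = a + rng.normal(scale=0.1, size=a.shape)
        sel = Selection("all", np.arange(8))
        r_ab = rmsd_series(traj_builder([a, b]), sel,
                           Frame(time=0, positions=a, box=np.full(3, 10.0))).values[1]
        r_ba = rmsd_series(traj_builder([b, a]), sel,
                           Frame(time=0, positions=b, box=np.full(3, 10.0))).values[1]
        assert r_ab == pytest.approx(r_ba, abs=1e-9)

    def test_empty_selection_rejected(self, traj_builder):
        traj = traj_builder([np.random.default_rng(0).normal(size=(4, 3))] * 2)
        with pytest.raises(ValueError, match="empty"):
            rmsd_series(traj, Selection("none", np.array([], dtype=int)), traj.frames[0])


class TestRmsf:
    def test_static_trajectory_zero(self, traj_builder):
        coords = np.random.default_rng(7).normal(size=(5, 3)) + 5
        traj = traj_builder([coords] * 6)
        prof = rmsf_profile(traj, Selection("all", np.arange(5)))
        np.testing.assert_allclose(prof.values, 0, atol=1e-12)

    def test_single_oscillating_atom_closed_form(self, traj_builder):
        """A light atom swinging +-d among heavy anchors fluctuates by d."""
        anchors = np.array([[0.0, 0, 0], [2.0, 0, 0], [0, 2.0, 0], [0, 0, 2.0]]) + 5
        d = 0.25
        frames = [np.vstack([anchors, [5 + sign * d, 5, 5]])
                  for sign in (+1, -1, +1, -1)]
        masses = np.array([1e6, 1e6, 1e6, 1e6, 1.0])
        traj = traj_builder(frames, masses=masses)
        prof = rmsf_profile(traj, Selection("all", np.arange(5)))
        assert prof.values[4] == pytest.approx(d, rel=1e-3)
        np.testing.assert_allclose(prof.values[:4], 0, atol=1e-3)

    def test_global_rotation_invariance(self, traj_builder):
        rng = np.random.default_rng(8)
        frames = [rng.normal(size=(6, 3)) + 5 for _ in range(5)]
        R = random_rotation(rng)
        sel = Selection("all", np.arange(6))
        p1 = rmsf_profile(traj_builder(frames), sel)
        p2 = rmsf_profile(traj_builder([f @ R.T for f in frames]), sel)
        np.testing.assert_allclose(p1.values, p2.values, atol=1e-8)

    def test_single_frame_rejected(self, traj_builder):
        traj = traj_builder([np.random.default_rng(0).normal(size=(4, 3))])
        with pytest.raises(ValueError, match="2 frames"):
            rmsf_profile(traj, Selection("all", np.arange(4)))


class TestCommonPca:
    def test_rank_one_breathing_ensemble(self, traj_builder):
        """Frames on a line in conformation space: only one non-zero mode.

        A uniform breathing mode (scaling about the centroid) is invariant
        under the superposition step, so the rank-1 structure is exact.
        """
        rng = np.random.default_rng(9)
        base = rng.normal(size=(5, 3)) + 5
        centroid = base.mean(axis=0)
        frames = [centroid + (1 + t) * (base - centroid)
                  for t in rng.normal(scale=0.1, size=30)]
        traj = traj_builder(frames, box=(100, 100, 100))
        res = common_pca([traj], Selection("all", np.arange(5)), mass_weighted=False)
        total = res.eigenvalues.sum()
        assert res.eigenvalues[1:].sum() <= 1e-10 * total
        # eigenvalue sum equals the pooled positional variance (exact here
        # because the superposition is the identity for every frame)
        stacked = np.stack(frames).reshape(30, -1)
        pooled_var = ((stacked - stacked.mean(axis=0)) ** 2).sum(axis=1).mean()
        assert total == pytest.approx(pooled_var, rel=1e-8)

    def test_mode_variance_recovery(self, traj_builder):
        """Gaussian ensemble with mode variances (4, 1, 0.25) is recovered."""
        rng = np.random.default_rng(11)
        frames = three_mode_ensemble(rng, n_frames=5000, sds=(2.0, 1.0, 0.5))
        traj = traj_builder(frames, box=(1000, 1000, 1000))
        res = common_pca([traj], Selection("all", np.arange(4)), mass_weighted=False)
        assert res.eigenvalues[0] == pytest.approx(4.0, rel=0.10)
        assert res.eigenvalues[1] == pytest.approx(1.0, rel=0.10)
        assert res.eigenvalues[2] == pytest.approx(0.25, rel=0.10)
        assert res.eigenvalues[3:].sum() < 0.05 * res.eigenvalues.sum()

    def test_projection_of_mean_is_origin(self, traj_builder):
        rng = np.random.default_rng(12)
        frames = [rng.normal(size=(5, 3)) + 5 for _ in range(25)]
        traj = traj_builder(frames)
        res = common_pca([traj], Selection("all", np.arange(5)), mass_weighted=False)
        np.testing.assert_allclose(res.projections["traj0"].mean(axis=0), 0, atol=1e-9)

    def test_components_orthonormal(self, traj_builder):
        rng = np.random.default_rng(14)
        frames = [rng.normal(size=(4, 3)) + 5 for _ in range(30)]
        res = common_pca([traj_builder(frames)], Selection("all", np.arange(4)),
                         mass_weighted=False)
        gram = res.components @ res.components.T
        np.testing.assert_allclose(gram, np.eye(len(res.components)), atol=1e-8)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)  # descending

    def test_shared_axes_across_trajectories(self, traj_builder):
        """Projections of two trajectories live on one common basis."""
        rng = np.random.default_rng(15)
        base = rng.normal(size=(5, 3)) + 5
        centroid = base.mean(axis=0)
        t1 = traj_builder([centroid + (1 + t) * (base - centroid)
                           for t in rng.normal(scale=0.05, size=20)], box=(100,) * 3)
        t2 = traj_builder([centroid + (1 + t) * (base - centroid)
                           for t in rng.normal(scale=0.2, size=20)], box=(100,) * 3)
        res = common_pca([t1, t2], Selection("all", np.arange(5)),
                         labels=["narrow", "wide"], mass_weighted=False)
        # same single mode: the wide ensemble spans a larger PC1 range
        assert np.ptp(res.projections["wide"][:, 0]) > np.ptp(res.projections["narrow"][:, 0])
        assert res.eigenvalues[1:].sum() <= 1e-9 * res.eigenvalues.sum()

    def test_selection_size_mismatch_rejected(self, traj_builder):
        t1 = traj_builder([np.random.default_rng(0).normal(size=(5, 3))] * 4)
        t2 = traj_builder([np.random.default_rng(0).normal(size=(6, 3))] * 4)
        with pytest.raises(ValueError, match="selection sizes"):
            common_pca([t1, t2], [Selection("a", np.arange(5)),
                                  Selection("b", np.arange(6))])


class TestSpanArea:
    def test_unit_right_triangle(self):
        assert pc_span_area(np.array([[0, 0], [1, 0], [0, 1.0]])) == pytest.approx(0.5)

    def test_duplicates_do_not_change_hull(self):
        pts = np.array([[0, 0], [1, 0], [0, 1.0], [0.2, 0.2]])
        base = pc_span_area(pts)
        assert pc_span_area(np.vstack([pts, pts])) == pytest.approx(base)

    def test_against_gift_wrapping_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(3):
            pts = rng.normal(size=(100, 2))
            assert pc_span_area(pts) == pytest.approx(jarvis_hull_area(pts), abs=1e-9)

    def test_collinear_and_tiny_inputs(self):
        with pytest.warns(UserWarning):
            assert pc_span_area(np.array([[0, 0], [1, 1.0]])) == 0.0
        line = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.warns(UserWarning):
            assert pc_span_area(line) == 0.0
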