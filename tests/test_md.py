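"""Trajectory analysis: superposition, RMSD/RMSF, persistence.

Superposition is validated against a rotation-grid oracle (Euler-angle
scan), RMSF against the closed form for isotropic jitter, and persistence
against exactly planted frame masks.
"""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from zincscreen.md import (
    InteractionSpec,
    Selection,
    Trajectory,
    interaction_mask,
    persistence,
    rmsd_series,
    rmsf,
    summarize,
    superpose,
)
from zincscreen.synthetic import (
    PlantedInteraction,
    TrajectorySpec,
    gen_trajectory,
)


def grid_oracle_rmsd(ref, mob, step_deg=2.0):
    """Minimum RMSD over a dense Euler-angle grid of proper rotations
    (independent of the analytic Kabsch path)."""
    ref = np.asarray(ref, float)
    mob = np.asarray(mob, float)
    ref0 = ref - ref.mean(0)
    mob0 = mob - mob.mean(0)
    a = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    b = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    angles = np.stack(np.meshgrid(a, b, a, indexing="ij"), axis=-1).reshape(-1, 3)
    best = np.inf
    chunk = 200_000
    for i in range(0, len(angles), chunk):
        mats = Rotation.from_euler("zyz", angles[i:i + chunk]).as_matrix()
        moved = np.einsum("rij,nj->rni", mats, mob0)
        rmsds = np.sqrt(np.mean(np.sum((moved - ref0) ** 2, axis=2), axis=1))
        best = min(best, float(rmsds.min()))
    return best


class TestSuperpose:
    def test_identical_sets_give_zero_and_identity(self, rng):
        pts = rng.uniform(-5, 5, (6, 3))
        transform, fit = superpose(pts, pts)
        assert fit == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(transform.rotation, np.eye(3), atol=1e-8)

    def test_pure_translation_removed(self, rng):
        pts = rng.uniform(-5, 5, (5, 3))
        transform, fit = superpose(pts, pts + np.array([3.0, -2.0, 9.0]))
        assert fit == pytest.approx(0.0, abs=1e-6)

    def test_proper_rotation_only(self, rng):
        pts = rng.uniform(-5, 5, (7, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        transform, _ = superpose(pts, mirrored)
        assert np.linalg.det(transform.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_rotation_grid_oracle(self, rng):
        """Asymmetric 5-point set vs a rotated noisy copy: the analytic fit
        equals an exhaustive 2-degree Euler-grid search to 0.01 Å."""
        pts = rng.uniform(-4, 4, (5, 3))
        rot = Rotation.random(random_state=np.random.RandomState(3)).as_matrix()
        noisy = pts @ rot.T + rng.normal(0, 0.3, (5, 3)) + 5.0
        _, fit = superpose(pts, noisy)
        oracle = grid_oracle_rmsd(pts, noisy)
        assert fit <= oracle + 1e-9          # Kabsch is the true optimum
        assert abs(fit - oracle) <= 0.01

    def test_collinear_points_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        with pytest.raises(ValueError, match="non-collinear"):
            superpose(line, line)


class TestRmsdSeries:
    def test_static_trajectory_is_all_zero(self, pocket):
        traj, _, _ = gen_trajectory(pocket, TrajectorySpec(n_frames=10, seed=1))
        series = rmsd_series(traj, Selection("protein_backbone"), Selection("ligand"))
        assert np.allclose(series, 0.0, atol=1e-9)
        assert len(series) == traj.n_frames

    def test_first_element_zero_for_frame0_reference(self, pocket):
        traj, _, _ = gen_trajectory(
            pocket, TrajectorySpec(n_frames=50, jitter_ligand=0.2, seed=2)
        )
        series = rmsd_series(traj, Selection("protein_backbone"), Selection("ligand"))
        assert series[0] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_ligand_displacement_reads_exactly(self, pocket):
        """Backbone fixed, ligand displaced 2 Å: ligand RMSD reads 2.0."""
        traj, _, _ = gen_trajectory(
            pocket, TrajectorySpec(n_frames=5, ligand_drift=(2.0, 0.0, 0.0), seed=3)
        )
        series = rmsd_series(traj, Selection("protein_backbone"), Selection("ligand"))
        assert series[-1] == pytest.approx(2.0, abs=1e-9)
        assert np.allclose(series, np.linspace(0, 2, 5), atol=1e-9)

    def test_termini_exclusion_changes_series_when_termini_move(self, pocket):
        traj, _, _ = gen_trajectory(pocket, TrajectorySpec(n_frames=8, seed=4))
        coords = traj.coords.copy()
        # jitter only the first residue (the 'terminus' of the pseudo chain)
        first_res = traj.atoms.index[
            (traj.atoms["role"] == "protein") & (traj.atoms["resid"] == 1)
        ].to_numpy()
        rng = np.random.default_rng(0)
        coords[1:, first_res, :] += rng.normal(0, 1.0, (coords.shape[0] - 1,
                                                        len(first_res), 3))
        moved = Trajectory(traj.atoms, coords, traj.dt_ns)
        incl = rmsd_series(moved, Selection("protein_backbone"),
                           Selection("protein_backbone"))
        excl_sel = Selection("protein_backbone", exclude_resids=((1, 1),))
        excl = rmsd_series(moved, excl_sel, excl_sel)
        assert not np.allclose(incl[1:], 0.0)
        assert np.allclose(excl[1:], 0.0, atol=1e-9)
        assert not np.allclose(incl, excl)

    def test_global_rigid_transform_invariance(self, pocket):
        traj, _, _ = gen_trajectory(
            pocket, TrajectorySpec(n_frames=6, jitter_ligand=0.3, seed=5)
        )
        base = rmsd_series(traj, Selection("protein_backbone"), Selection("ligand"))
        rot = Rotation.random(random_state=np.random.RandomState(4)).as_matrix()
        moved = Trajectory(traj.atoms, traj.coords @ rot.T + 11.0, traj.dt_ns)
        series = rmsd_series(moved, Selection("protein_backbone"), Selection("ligand"))
        assert np.allclose(series, base, atol=1e-8)

    def test_empty_selection_is_error(self, pocket):
        traj, _, _ = gen_trajectory(pocket, TrajectorySpec(n_frames=3, seed=6))
        with pytest.raises(ValueError, match="zero atoms"):
            rmsd_series(traj, Selection("protein_backbone"),
                        Selection("custom", indices=()))


class TestRmsf:
    def test_static_trajectory_gives_zeros(self, pocket):
        traj, _, _ = gen_trajectory(pocket, TrajectorySpec(n_frames=4, seed=7))
        vals = rmsf(traj, Selection("ligand"), Selection("protein_backbone"))
        assert np.allclose(vals, 0.0, atol=1e-9)

    def test_isotropic_jitter_converges_to_sqrt3_sigma(self, pocket):
        """Per-axis sigma = 0.5 Å over 2,000 frames: RMSF = sqrt(3)*sigma
        within 5%."""
        sigma = 0.5
        traj, _, _ = gen_trajectory(
            pocket, TrajectorySpec(n_frames=2000, jitter_ligand=sigma, seed=8)
        )
        vals = rmsf(traj, Selection("ligand"), Selection("protein_backbone"))
        target = np.sqrt(3.0) * sigma
        assert np.all(np.abs(vals / target - 1.0) < 0.05)

    def test_single_jittered_atom_localizes(self, pocket):
        traj, _, _ = gen_trajectory(pocket, TrajectorySpec(n_frames=100, seed=9))
        coords = traj.coords.copy()
        lig_idx = Selection("ligand").resolve(traj)
        rng = np.random.default_rng(1)
        coords[:, lig_idx[0], :] += rng.normal(0, 0.5, (coords.shape[0], 3))
        moved = Trajectory(traj.atoms, coords, traj.dt_ns)
        vals = rmsf(moved, Selection("ligand"))
        assert vals[0] > 0.3
        assert np.allclose(vals[1:], 0.0, atol=1e-9)

    def test_single_frame_rejected(self, pocket):
        traj, _, _ = gen_trajectory(pocket, TrajectorySpec(n_frames=1, seed=10))
        with pytest.raises(ValueError, match="two frames"):
            rmsf(traj, Selection("ligand"))


class TestPersistence:
    def test_all_frames_satisfied_gives_one(self, pocket):
        traj, specs, _ = gen_trajectory(
            pocket,
            TrajectorySpec(
                n_frames=50, seed=11,
                interactions=(PlantedInteraction("chel", "distance", 1.0,
                                                 max_distance=2.6),),
            ),
        )
        assert persistence(traj, specs[0]) == 1.0

    def test_planted_mask_recovered_exactly(self, pocket):
        """680 of 1,000 planted frames: persistence 0.680 exactly."""
        traj, specs, truth = gen_trajectory(
            pocket,
            TrajectorySpec(
                n_frames=1000, seed=12, jitter_ligand=0.1, jitter_protein=0.05,
                interactions=(
                    PlantedInteraction("hb_his", "hbond", 0.68),
                    PlantedInteraction("sb_his", "salt_bridge", 0.98),
                ),
            ),
        )
        assert persistence(traj, specs[0]) == pytest.approx(0.680, abs=0)
        assert persistence(traj, specs[1]) == pytest.approx(0.980, abs=0)
        mask = interaction_mask(traj, specs[0])
        assert np.array_equal(mask, truth["masks"]["hb_his"])

    def test_chelating_pose_frames_persist_at_cutoff(self, pocket):
        """The planted chelating template replicated as frames keeps both
        chelator oxygens within the chelation cutoff in every frame."""
        from zincscreen.poses import assess_chelation

        pose = pocket.template_pose()
        assert assess_chelation(pose, pocket.receptor).cls.value == "bidentate"
        traj, specs, _ = gen_trajectory(
            pocket,
            TrajectorySpec(
                n_frames=20, seed=13,
                interactions=(PlantedInteraction("chel", "distance", 1.0,
                                                 max_distance=2.6),),
            ),
        )
        assert persistence(traj, specs[0]) == 1.0

    def test_unresolvable_selector_is_error(self, pocket):
        traj, _, _ = gen_trajectory(pocket, TrajectorySpec(n_frames=3, seed=14))
        spec = InteractionSpec("bad", "distance",
                               (("a", (999, "XX")), ("b", 0)), max_distance=2.6)
        with pytest.raises(ValueError, match="resolves to 0"):
            persistence(traj, spec)


class TestSummarize:
    def test_summary_bundles_series_and_persistence(self, pocket, tmp_path):
        traj, specs, _ = gen_trajectory(
            pocket,
            TrajectorySpec(
                n_frames=40, seed=15, jitter_ligand=0.1,
                interactions=(PlantedInteraction("sb", "salt_bridge", 0.9),),
            ),
        )
        summary = summarize(traj, specs)
        assert set(summary.rmsd) >= {"protein_backbone", "ligand", "zinc"}
        assert len(summary.rmsd["ligand"]) == traj.n_frames
        assert summary.persistence["sb"] == 0.9
        summary.save_csv(tmp_path)
        text = (tmp_path / "persistence.csv").read_text()
        assert "sb" in text and "90.0" in text


class TestPdbRoundTrip:
    def test_multi_model_round_trip(self, pocket, tmp_path):
        traj, _, _ = gen_trajectory(
            pocket, TrajectorySpec(n_frames=5, jitter_ligand=0.2, seed=16)
        )
        path = tmp_path / "traj.pdb"
        traj.to_pdb(path)
        back = Trajectory.from_pdb(path)
        assert back.n_frames == traj.n_frames
        assert back.n_atoms == traj.n_atoms
        assert np.abs(back.coords - traj.coords).max() < 2e-3  # PDB precision
        assert list(back.atoms["role"]) == list(traj.atoms["role"])
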