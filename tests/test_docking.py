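"""Docking: scorer closed forms, grid fidelity, search recovery, pose
clustering and the largest-cluster reporting rule."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from vasite.docking import (
    GridMaps,
    Pose,
    cluster_poses,
    dock_blind,
    dock_focused,
    pose_rmsd,
    score_pose,
)
from vasite.structure_io import LigandTemplate, assign_params, load_element_params
from vasite.synthetic import (
    CavitySpec,
    TailSpec,
    build_ligand,
    make_toy_receptor,
    radius_of_gyration,
    receptor_ground_truth,
    sample_tail_conformers,
)
from tests.conftest import small_conformation

PARAMS = load_element_params()


def _ligand(template, torsions=None):
    return assign_params(build_ligand(template, torsions), PARAMS,
                         charges=template.charge_array)


def _single_atom_template(element="C"):
    radius = PARAMS[element][0]
    return LigandTemplate(atoms=[("X1", element, radius, 0.0)],
                          zmatrix=[(0.0, 0.0, 0.0, ())])


class TestScorePose:
    def test_beyond_cutoff_is_zero(self, halothane):
        receptor = small_conformation(np.zeros((1, 3)))
        ligand = _ligand(halothane)
        ligand = ligand.with_coords(ligand.coord + np.array([100.0, 0, 0]))
        e_vdw, e_elec, per_atom, clash = score_pose(receptor, ligand)
        assert e_vdw == 0.0 and e_elec == 0.0 and not clash

    def test_lj_minimum_closed_form(self):
        # one neutral C...Br pair at r = rmin gives exactly -sqrt(eps_C*eps_Br)
        receptor = small_conformation(np.zeros((1, 3)))
        template = _single_atom_template("BR")
        ligand = _ligand(template)
        rmin = PARAMS["C"][0] + PARAMS["BR"][0]
        ligand = ligand.with_coords(np.array([[rmin, 0.0, 0.0]]))
        e_vdw, e_elec, _pa, _cl = score_pose(receptor, ligand)
        assert e_vdw == pytest.approx(-np.sqrt(PARAMS["C"][1] * PARAMS["BR"][1]), abs=1e-12)
        assert e_elec == 0.0

    def test_coulomb_closed_form(self):
        receptor = small_conformation(np.zeros((1, 3)), charges=[0.5])
        template = LigandTemplate(atoms=[("X1", "C", 1.908, -0.2)],
                                  zmatrix=[(0.0, 0.0, 0.0, ())])
        ligand = _ligand(template)
        ligand = ligand.with_coords(np.array([[5.0, 0.0, 0.0]]))
        _ev, e_elec, _pa, _cl = score_pose(receptor, ligand)
        expected = 332.06 * 0.5 * -0.2 / (4.0 * 5.0 * 5.0)
        assert e_elec == pytest.approx(expected, abs=1e-12)

    def test_per_atom_decomposition_sums_to_totals(self, halothane, cavity_receptor):
        ligand = _ligand(halothane)
        e_vdw, e_elec, per_atom, _cl = score_pose(cavity_receptor, ligand)
        assert sum(v for _n, v, _e in per_atom) == pytest.approx(e_vdw, abs=1e-9)
        assert sum(e for _n, _v, e in per_atom) == pytest.approx(e_elec, abs=1e-9)

    def test_overlap_capped_not_nan(self, halothane):
        receptor = small_conformation(np.zeros((1, 3)))
        ligand = _ligand(halothane)
        ligand = ligand.with_coords(ligand.coord - ligand.coord[0])  # atom 0 on top
        e_vdw, _ee, _pa, clash = score_pose(receptor, ligand)
        assert clash and np.isfinite(e_vdw)

    def test_rigid_motion_invariance(self, halothane, cavity_receptor):
        ligand = _ligand(halothane)
        e0 = sum(score_pose(cavity_receptor, ligand)[:2])
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7])
        shift = np.array([5.0, -3.0, 2.0])
        receptor2 = cavity_receptor.with_coords(rot.apply(cavity_receptor.coord) + shift)
        ligand2 = ligand.with_coords(rot.apply(ligand.coord) + shift)
        e1 = sum(score_pose(receptor2, ligand2)[:2])
        assert e1 == pytest.approx(e0, abs=1e-6)


class TestGridFidelity:
    def test_interpolated_energy_tracks_direct_sum(self, halothane):
        # planar receptor sheet; poses sampled in the smooth attractive
        # regime (no wall contact), where grid fidelity is meaningful
        xs, ys = np.meshgrid(np.arange(-6, 7, 3.0), np.arange(-6, 7, 3.0))
        coords = np.stack([xs.ravel(), ys.ravel(), np.zeros(xs.size)], axis=1)
        receptor = small_conformation(coords,
                                      charges=np.tile([0.1, -0.1], xs.size)[: xs.size])
        ligand = _ligand(halothane)
        classes = [(float(r), float(e)) for r, e in zip(ligand.radius, ligand.epsilon)]
        center, edges = np.array([0.0, 0, 7.0]), np.array([8.0, 8.0, 5.0])
        maps = GridMaps(receptor, center, edges, 0.375, sorted(set(classes)))
        rng = np.random.default_rng(1)
        base = ligand.coord - ligand.coord.mean(axis=0)
        checked = 0
        for _ in range(200):
            t = center + (rng.random(3) - 0.5) * np.array([6.0, 6.0, 3.0])
            pose_coords = Rotation.random(rng=rng).apply(base) + t
            if pose_coords[:, 2].min() < 4.3:
                continue
            e_vdw, e_elec, _pa, _cl = score_pose(receptor, ligand.with_coords(pose_coords))
            grid_e = maps.energy(pose_coords, classes, ligand.partial_charge)
            assert abs(grid_e - (e_vdw + e_elec)) <= 0.1
            checked += 1
            if checked == 100:
                break
        assert checked == 100


class TestDockFocused:
    def test_recovers_cavity_against_translation_oracle(self, cavity_receptor, halothane):
        truth = receptor_ground_truth(cavity_receptor)["cavities"][0]
        center = np.array(truth["center"])
        result = dock_focused(cavity_receptor, halothane, center=center,
                              n_restarts=8, n_local_steps=120, seed=3)
        best = min(result.poses, key=lambda p: p.e_total)
        assert np.linalg.norm(best.coords.mean(axis=0) - center) < 2.0

        # exhaustive coarse oracle: rigid ligand on a 1 A translation grid
        ligand = _ligand(halothane)
        base = ligand.coord - ligand.coord.mean(axis=0)
        grid = np.arange(-5.0, 5.01, 1.0)
        best_oracle, best_t = np.inf, None
        for x in grid:
            for y in grid:
                for z in grid:
                    t = center + np.array([x, y, z])
                    ev, ee, _pa, _cl = score_pose(cavity_receptor, ligand.with_coords(base + t))
                    if ev + ee < best_oracle:
                        best_oracle, best_t = ev + ee, t
        assert np.linalg.norm(best_t - center) < 2.0  # oracle agrees on location
        assert result.best_energy <= best_oracle + 0.5  # search at least as good

    def test_seed_determinism(self, cavity_receptor, halothane):
        kwargs = dict(center=[0.0, 0.0, 0.0], n_restarts=4, n_local_steps=80, seed=11)
        a = dock_focused(cavity_receptor, halothane, **kwargs)
        b = dock_focused(cavity_receptor, halothane, **kwargs)
        assert len(a.poses) == len(b.poses)
        for pa, pb in zip(a.poses, b.poses):
            np.testing.assert_array_equal(pa.coords, pb.coords)
            assert pa.e_total == pb.e_total

    def test_vdw_dominates_with_halogens_on_top(self, cavity_receptor, halothane):
        result = dock_focused(cavity_receptor, halothane, center=[0.0, 0.0, 0.0],
                              n_restarts=8, n_local_steps=120, seed=5)
        best = min(result.poses, key=lambda p: p.e_total)
        assert best.e_total < 0
        assert abs(best.e_vdw) > abs(best.e_elec)
        by_vdw = sorted(best.per_atom, key=lambda t: t[1])
        top_two = {name for name, _v, _e in by_vdw[:2]}
        assert top_two & {"CL1", "BR1"}
        assert {"CL1", "BR1"} & {name for name, _v, _e in by_vdw[:3]}

    def test_energy_components_consistent(self, cavity_receptor, halothane):
        result = dock_focused(cavity_receptor, halothane, center=[0.0, 0.0, 0.0],
                              n_restarts=3, n_local_steps=60, seed=2)
        for pose in result.poses:
            assert pose.e_total == pytest.approx(pose.e_vdw + pose.e_elec, abs=1e-9)
            assert np.linalg.norm(pose.orientation) == pytest.approx(1.0, abs=1e-9)
        assert result.best_energy == min(p.e_total for p in result.poses)
        assert sum(len(c) for c in result.clusters) == len(result.poses)


class TestDockBlind:
    def test_single_atom_molecule_settles_at_lj_optimum(self):
        molecule = small_conformation(np.zeros((1, 3)))
        template = _single_atom_template("C")
        result = dock_blind(molecule, template, grid_spacing=0.25, margin=3.0,
                            n_restarts=6, n_local_steps=100, seed=1)
        best = min(result.poses, key=lambda p: p.e_total)
        rmin = 2 * PARAMS["C"][0]
        assert np.linalg.norm(best.coords[0]) == pytest.approx(rmin, abs=0.1)
        assert best.e_total == pytest.approx(-PARAMS["C"][1], abs=0.005)

    def test_compact_tail_binds_stronger_than_extended(self, halothane):
        conformers = sample_tail_conformers(
            TailSpec("DATADEQGEFEEEEGEDEA", n_conformers=8, seed=3))
        extended, compact = conformers[0], conformers[7]
        assert radius_of_gyration(extended) > 1.5 * radius_of_gyration(compact)
        kwargs = dict(grid_spacing=0.75, margin=4.0, n_restarts=6,
                      n_local_steps=120, seed=4)
        e_ext = dock_blind(extended, halothane, **kwargs).reported_energy
        e_cmp = dock_blind(compact, halothane, **kwargs).reported_energy
        assert e_cmp < e_ext < 0

    def test_empty_molecule_rejected(self, halothane, cavity_receptor):
        empty = cavity_receptor.select(np.zeros(cavity_receptor.n_atoms, dtype=bool))
        with pytest.raises(ValueError):
            dock_blind(empty, halothane)


def _pose(coords, energy):
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    return Pose(translation=coords.mean(axis=0), orientation=np.array([0, 0, 0, 1.0]),
                torsion_angles={}, coords=coords, e_vdw=energy, e_elec=0.0,
                e_total=energy, per_atom=[])


class TestClusterPoses:
    def test_all_close_single_cluster(self):
        poses = [_pose([[0.1 * i, 0, 0]], -5.0 + 0.1 * i) for i in range(5)]
        clusters, reported = cluster_poses(poses)
        assert len(clusters) == 1
        assert reported == pytest.approx(-5.0)

    def test_largest_cluster_rule_beats_global_best(self):
        # 7-pose family near the origin, 3-pose family (incl. global best)
        # far away: the reported energy comes from the larger family
        family_a = [_pose([[0.2 * i, 0, 0]], -5.0 + 0.05 * i) for i in range(7)]
        family_b = [_pose([[20 + 0.2 * i, 0, 0]], -8.0 + 0.05 * i) for i in range(3)]
        clusters, reported = cluster_poses(family_a + family_b)
        assert sorted(len(c) for c in clusters) == [3, 7]
        assert reported == pytest.approx(-5.0)
        assert min(p.e_total for p in family_b) == pytest.approx(-8.0)  # ignored

    def test_size_tie_goes_to_lower_energy(self):
        family_a = [_pose([[0.2 * i, 0, 0]], -5.0 + 0.05 * i) for i in range(3)]
        family_b = [_pose([[20 + 0.2 * i, 0, 0]], -8.0 + 0.05 * i) for i in range(3)]
        _clusters, reported = cluster_poses(family_a + family_b)
        assert reported == pytest.approx(-8.0)

    def test_matches_brute_force_leader_oracle(self):
        rng = np.random.default_rng(9)
        poses = [_pose(rng.uniform(0, 15, size=(2, 3)), float(rng.normal(-5, 1)))
                 for _ in range(20)]
        clusters, _reported = cluster_poses(poses, rmsd_cutoff=2.0)

        # independent re-derivation of energy-ordered leader clustering
        order = sorted(range(20), key=lambda i: poses[i].e_total)
        remaining = list(order)
        expected = []
        while remaining:
            leader = remaining[0]
            members = [i for i in remaining if pose_rmsd(poses[leader], poses[i]) <= 2.0]
            expected.append(sorted(members))
            remaining = [i for i in remaining if i not in members]
        assert sorted(map(sorted, clusters)) == sorted(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cluster_poses([])
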