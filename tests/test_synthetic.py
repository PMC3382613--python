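"""Synthetic generators: receptors, ensembles, tails, ligand geometry."""

import numpy as np
import pytest

from vasite.clustering import pairwise_rmsd, single_linkage_cluster
from vasite.structure_io import StructureError
from vasite.synthetic import (
    CavitySpec,
    TailSpec,
    build_ligand,
    dihedral_angle,
    internal_coords,
    make_toy_receptor,
    make_two_regime_ensemble,
    perturb_ensemble,
    radius_of_gyration,
    receptor_ground_truth,
    sample_tail_conformers,
    zmatrix_to_cartesian,
)
from vasite.structure_io import LigandTemplate


class TestToyReceptor:
    def test_seed_determinism(self):
        spec = [CavitySpec(center=np.array([0.0, 0.0, 4.5]))]
        a = make_toy_receptor(spec, seed=9)
        b = make_toy_receptor(spec, seed=9)
        np.testing.assert_array_equal(a.coord, b.coord)
        assert list(a.res_name) == list(b.res_name)

    def test_overlapping_cavities_rejected(self):
        specs = [CavitySpec(center=np.zeros(3)), CavitySpec(center=np.array([1.0, 0, 0]))]
        with pytest.raises(StructureError, match="overlap"):
            make_toy_receptor(specs)

    def test_protruding_cavity_rejected(self):
        with pytest.raises(StructureError, match="protrude"):
            make_toy_receptor([CavitySpec(center=np.array([0.0, 0.0, 8.0]))])

    def test_ground_truth_sidecar(self, two_cavity_receptor):
        truth = receptor_ground_truth(two_cavity_receptor)
        assert len(truth["cavities"]) == 2
        np.testing.assert_allclose(truth["cavities"][0]["center"], [0, 0, 4.5])
        lo, hi = truth["cavities"][0]["lining_residues"]
        assert 0 < lo <= hi <= two_cavity_receptor.n_atoms

    def test_lining_hydrophobic_fraction_honored(self):
        rec = make_toy_receptor(
            [CavitySpec(center=np.zeros(3), lining_hydrophobic_fraction=0.5)], seed=2)
        truth = receptor_ground_truth(rec)
        lo, hi = truth["cavities"][0]["lining_residues"]
        lining = rec.select((rec.res_id >= lo) & (rec.res_id <= hi))
        frac = lining.hydrophobic_heavy_mask.mean()
        assert abs(frac - 0.5) < 0.05


class TestPerturbEnsemble:
    def test_zero_backbone_amplitude_fixes_backbone(self, two_cavity_receptor):
        base = two_cavity_receptor
        mask = np.zeros(base.n_atoms, dtype=bool)
        mask[::3] = True
        ens = perturb_ensemble(base, n_frames=4, sidechain_amp=0.8,
                               backbone_amp=0.0, backbone_mask=mask, seed=0)
        for conf in ens:
            np.testing.assert_array_equal(conf.coord[mask], base.coord[mask])

    def test_amplitude_bounds_rmsd(self, two_cavity_receptor):
        base = two_cavity_receptor
        mask = np.zeros(base.n_atoms, dtype=bool)
        mask[: base.n_atoms // 2] = True
        bb_amp, sc_amp = 0.2, 0.8
        ens = perturb_ensemble(base, 251 // 5, sidechain_amp=sc_amp,
                               backbone_amp=bb_amp, backbone_mask=mask, seed=1)
        n_bb = int(mask.sum())
        bound = np.sqrt((n_bb * bb_amp**2 + (base.n_atoms - n_bb) * sc_amp**2)
                        / base.n_atoms)
        for conf in ens:
            assert pairwise_rmsd(base, conf, superpose_first=False) <= bound + 1e-9

    def test_single_frame_minimum(self, two_cavity_receptor):
        with pytest.raises(ValueError):
            perturb_ensemble(two_cavity_receptor, n_frames=0)

    def test_regime_offset_recovers_two_clusters(self, two_cavity_receptor):
        base = two_cavity_receptor
        mask = np.zeros(base.n_atoms, dtype=bool)
        mask[::2] = True
        ens = perturb_ensemble(base, n_frames=20, sidechain_amp=0.15,
                               backbone_amp=0.05, seed=3,
                               regime_boundary=12, regime_mask=mask,
                               regime_offset=np.array([3.0, 0.0, 0.0]))
        clusters = single_linkage_cluster(ens, cutoff=1.0)
        assert sorted(c.n_members for c in clusters) == [8, 12]
        big = max(clusters, key=lambda c: c.n_members)
        assert big.member_frames == frozenset(range(12))


class TestTwoRegimeEnsemble:
    def test_regimes_separate_and_close_cavity(self):
        ens, truth = make_two_regime_ensemble(n_frames=8, boundary=4, seed=0)
        assert truth["regime_boundary"] == 4
        inter = pairwise_rmsd(ens[0], ens[5])
        intra = pairwise_rmsd(ens[0], ens[1])
        assert inter > 1.0 > intra

    def test_seed_determinism(self):
        a, _ = make_two_regime_ensemble(n_frames=4, boundary=2, seed=5)
        b, _ = make_two_regime_ensemble(n_frames=4, boundary=2, seed=5)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.coord, cb.coord)


class TestTailConformers:
    def test_table_sequence_counts(self):
        ens = sample_tail_conformers(
            TailSpec("DATADEQGEFEEEEGEDEA", n_conformers=50, seed=0))
        assert ens.total_frames == 50
        for conf in ens:
            assert len(set(conf.res_id)) == 19
            assert conf.n_atoms == 38  # two pseudo-atoms per residue

    def test_self_avoidance(self):
        ens = sample_tail_conformers(TailSpec("DATADEQGEFEEEEGEDEA",
                                              n_conformers=10, seed=1))
        for conf in ens:
            d = np.linalg.norm(conf.coord[:, None] - conf.coord[None, :], axis=-1)
            n = conf.n_atoms
            d[np.arange(n), np.arange(n)] = np.inf
            ca = np.arange(n // 2) * 2
            d[ca[:-1], ca[1:]] = d[ca[1:], ca[:-1]] = np.inf
            d[ca, ca + 1] = d[ca + 1, ca] = np.inf
            assert d.min() >= 2.0

    def test_compactness_spread(self):
        ens = sample_tail_conformers(TailSpec("DATADEQGEFEEEEGEDEA",
                                              n_conformers=50, seed=2))
        rgs = [radius_of_gyration(c) for c in ens]
        assert max(rgs) / min(rgs) >= 1.5

    def test_seed_determinism(self):
        a = sample_tail_conformers(TailSpec("DYEEVGVDSVEGEEEGEEY", 1, seed=7))
        b = sample_tail_conformers(TailSpec("DYEEVGVDSVEGEEEGEEY", 1, seed=7))
        np.testing.assert_array_equal(a[0].coord, b[0].coord)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            TailSpec("", 1)


class TestLigandBuilder:
    def test_collinear_chain(self):
        tpl = LigandTemplate(
            atoms=[("A", "C", 1.9, 0.0)] * 3,
            zmatrix=[(0.0, 0.0, 0.0, ()), (1.5, 0.0, 0.0, (0,)),
                     (1.5, 180.0, 0.0, (1, 0))],
        )
        conf = build_ligand(tpl)
        assert np.linalg.norm(conf.coord[2] - conf.coord[0]) == pytest.approx(3.0, abs=1e-9)

    def test_halothane_round_trip(self, halothane):
        conf = build_ligand(halothane)
        recomputed = internal_coords(conf.coord, halothane.zmatrix)
        for k, ((length, angle, dihedral, _refs), (length2, angle2, dihedral2)) in enumerate(
                zip(halothane.zmatrix, recomputed)):
            if k >= 1:
                assert length2 == pytest.approx(length, abs=1e-6)
            if k >= 2:
                assert angle2 == pytest.approx(angle, abs=1e-4)
            if k >= 3:
                delta = (dihedral2 - dihedral + 180.0) % 360.0 - 180.0
                assert abs(delta) < 1e-4

    def test_dihedral_sign_gives_mirror_images(self):
        rows = [(0.0, 0.0, 0.0, ()), (1.5, 0.0, 0.0, (0,)),
                (1.4, 109.5, 0.0, (1, 0)), (1.3, 109.5, 90.0, (2, 1, 0))]
        plus = zmatrix_to_cartesian(rows)
        rows[3] = (1.3, 109.5, -90.0, (2, 1, 0))
        minus = zmatrix_to_cartesian(rows)
        # first three atoms lie in the y=0... construction plane; the fourth
        # reflects through it when the dihedral sign flips
        np.testing.assert_allclose(plus[:3], minus[:3], atol=1e-9)
        assert dihedral_angle(plus[3], plus[2], plus[1], plus[0]) == pytest.approx(90.0, abs=1e-6)
        assert dihedral_angle(minus[3], minus[2], minus[1], minus[0]) == pytest.approx(-90.0, abs=1e-6)
        np.testing.assert_allclose(np.linalg.norm(plus[3] - plus[0]),
                                   np.linalg.norm(minus[3] - minus[0]), atol=1e-9)

    def test_zero_angle_rejected(self):
        rows = [(0.0, 0.0, 0.0, ()), (1.5, 0.0, 0.0, (0,)),
                (1.4, 109.5, 0.0, (1, 0)), (1.3, 0.0, 0.0, (2, 1, 0))]
        with pytest.raises(StructureError, match="angle"):
            zmatrix_to_cartesian(rows)

    def test_torsion_offsets_rotate_group(self, halothane):
        base = build_ligand(halothane).coord
        turned = build_ligand(halothane, torsion_offsets={5: 120.0}).coord
        # CF3 group unmoved, CHClBr substituents rotate together
        np.testing.assert_allclose(base[:5], turned[:5], atol=1e-9)
        assert np.linalg.norm(base[5] - turned[5]) > 0.5
        d_cl_h = np.linalg.norm(base[6] - base[5])
        assert np.linalg.norm(turned[6] - turned[5]) == pytest.approx(d_cl_h, abs=1e-6)
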