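"""Active-site geometry audit: attack distance, oxyanion hole, triad, energies."""

import numpy as np
import pytest

from rescaffold.model_io import AtomRecord, ResidueRecord, StructureModel
from rescaffold.active_site_audit import (LigandPose, TriadAssignment,
                                          attack_distance,
                                          find_oxyanion_donors,
                                          triad_geometry, energy_window_filter,
                                          audit_active_site, parse_pose_table,
                                          annotate_ester_groups)
from rescaffold.fixtures import (make_pose_at_distance, default_triad,
                                 _write_pose, _ESTER_TEMPLATE)
from conftest import rigidly_move


def simple_ester(c1, direction=np.array([0.0, 0.0, 1.0])):
    """Minimal annotated ester group with the carbonyl carbon at ``c1``."""
    c1 = np.asarray(c1, dtype=float)
    return [
        ("C1", "C", c1),
        ("O1", "O", c1 + 1.23 * direction),
        ("O2", "O", c1 + np.array([1.27, 0.0, -0.45])),
    ]


class TestAttackDistance:
    def test_constructed_distance(self, scaffold40, triad40):
        pose = make_pose_at_distance(scaffold40, triad40, 3.0, seed=0)
        assert attack_distance(scaffold40, triad40, pose) == pytest.approx(
            3.0, abs=1e-6)

    @pytest.mark.parametrize("d, passes", [
        (3.0, True), (3.99, True), (4.0, False),
    ])
    def test_strict_4A_criterion(self, scaffold40, triad40, d, passes):
        pose = make_pose_at_distance(scaffold40, triad40, d, seed=1)
        value = attack_distance(scaffold40, triad40, pose)
        assert (value < 4.0) is passes

    def test_minimum_over_ester_groups(self, scaffold40, triad40):
        # three carbonyl carbons at 6.1 / 3.4 / 5.0 Å: the audit reports 3.4
        og = scaffold40.residue(*triad40.ser).atom(triad40.ser_atom).coords
        atoms = []
        groups = []
        for direction, d in zip(np.eye(3), (6.1, 3.4, 5.0)):
            c1 = og + d * direction
            base = len(atoms)
            atoms.extend(simple_ester(c1))
            groups.append((base, base + 1, base + 2))
        pose = LigandPose(atoms=atoms, ester_groups=groups)
        got = attack_distance(scaffold40, triad40, pose)
        # brute-force oracle: min over every annotated carbonyl carbon
        oracle = min(np.linalg.norm(og - atoms[ci][2]) for ci, _, _ in groups)
        assert got == pytest.approx(oracle, abs=1e-9)
        assert got == pytest.approx(3.4, abs=1e-6)

    def test_no_ester_groups_errors(self, scaffold40, triad40):
        pose = LigandPose(atoms=simple_ester([0, 0, 0]), ester_groups=[])
        with pytest.raises(ValueError):
            attack_distance(scaffold40, triad40, pose)

    def test_monotone_in_added_groups(self, scaffold40, triad40):
        og = scaffold40.residue(*triad40.ser).atom(triad40.ser_atom).coords
        atoms = simple_ester(og + np.array([5.0, 0, 0]))
        pose1 = LigandPose(atoms=atoms, ester_groups=[(0, 1, 2)])
        d1 = attack_distance(scaffold40, triad40, pose1)
        atoms2 = atoms + simple_ester(og + np.array([0, 3.0, 0]))
        pose2 = LigandPose(atoms=atoms2, ester_groups=[(0, 1, 2), (3, 4, 5)])
        assert attack_distance(scaffold40, triad40, pose2) <= d1


def _model_with_backbone_n(positions):
    residues = []
    for i, pos in enumerate(positions):
        residues.append(ResidueRecord("A", i + 1, " ", "GLY", [
            AtomRecord(2 * i + 1, "N", "N", np.asarray(pos, dtype=float)),
            AtomRecord(2 * i + 2, "CA", "C",
                       np.asarray(pos, dtype=float) + [1.5, 0, 0]),
        ]))
    return StructureModel(1, residues, provenance="synthetic")


class TestOxyanionDonors:
    def test_two_donors_at_2p9(self):
        # two backbone NH groups 2.9 Å from the carbonyl O form the hole
        o = np.array([0.0, 0.0, 0.0])
        model = _model_with_backbone_n([o + [0, 2.9, 0], o + [0, 0, 2.9],
                                        o + [0, -8.0, 0]])
        pose = LigandPose(atoms=simple_ester(o - [0, 0, 1.23]),
                          ester_groups=[(0, 1, 2)])
        donors = find_oxyanion_donors(model, pose, 0)
        assert len(donors) == 2
        assert all(d == pytest.approx(2.9, abs=1e-9) for _, d in donors)

    def test_donors_beyond_cutoff_excluded(self):
        o = np.array([0.0, 0.0, 0.0])
        model = _model_with_backbone_n([o + [0, 3.6, 0], o + [0, 0, 4.0]])
        pose = LigandPose(atoms=simple_ester(o - [0, 0, 1.23]),
                          ester_groups=[(0, 1, 2)])
        assert find_oxyanion_donors(model, pose, 0) == []

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        o = np.zeros(3)
        positions = [o + rng.uniform(-5, 5, 3) for _ in range(5)]
        model = _model_with_backbone_n(positions)
        pose = LigandPose(atoms=simple_ester(o - [0, 0, 1.23]),
                          ester_groups=[(0, 1, 2)])
        donors = find_oxyanion_donors(model, pose, 0, max_NO_dist=3.5)
        carbonyl_o = pose.atoms[1][2]
        oracle = sorted(
            [(r.key, float(np.linalg.norm(r.atom("N").coords - carbonyl_o)))
             for r in model.residues
             if np.linalg.norm(r.atom("N").coords - carbonyl_o) <= 3.5],
            key=lambda x: x[1])
        assert donors == oracle

    def test_invalid_group_index(self, scaffold40):
        pose = LigandPose(atoms=simple_ester([0, 0, 0]), ester_groups=[(0, 1, 2)])
        with pytest.raises(ValueError):
            find_oxyanion_donors(scaffold40, pose, 5)


class TestTriadGeometry:
    def test_planted_ideal_triad(self, scaffold40, triad40):
        g = triad_geometry(scaffold40, triad40)
        assert g["ser_OG_his_NE2"] == pytest.approx(3.0, abs=1e-6)
        assert g["his_ND1_asp_O"] == pytest.approx(2.8, abs=1e-6)
        assert g["hbonded"]

    def test_distant_asp_breaks_hbond_flag(self):
        from rescaffold.fixtures import ToyScaffoldParams, make_toy_scaffold
        model = make_toy_scaffold(ToyScaffoldParams(
            n_residues=40, triad_targets=(3.0, 5.5), seed=2))
        g = triad_geometry(model, default_triad(model))
        assert g["his_ND1_asp_O"] == pytest.approx(5.5, abs=1e-6)
        assert not g["hbonded"]

    def test_random_triads_match_coordinate_arithmetic(self):
        from rescaffold.fixtures import ToyScaffoldParams, make_toy_scaffold
        rng = np.random.default_rng(5)
        for k in range(20):
            t1 = float(rng.uniform(2.5, 5.9))
            t2 = float(rng.uniform(2.5, 5.9))
            model = make_toy_scaffold(ToyScaffoldParams(
                n_residues=30, triad_targets=(t1, t2), seed=k))
            triad = default_triad(model)
            g = triad_geometry(model, triad)
            # direct recomputation from raw coordinates
            og = model.residue(*triad.ser).atom("OG").coords
            his = model.residue(*triad.his)
            asp = model.residue(*triad.asp)
            d_ser = np.linalg.norm(og - his.atom("NE2").coords)
            d_asp = min(np.linalg.norm(his.atom("ND1").coords
                                       - asp.atom(n).coords)
                        for n in ("OD1", "OD2"))
            assert g["ser_OG_his_NE2"] == pytest.approx(d_ser, abs=1e-9)
            assert g["his_ND1_asp_O"] == pytest.approx(d_asp, abs=1e-9)

    def test_missing_atom_named_in_error(self, scaffold40):
        bad = TriadAssignment(ser=("A", 1), his=("A", 21), asp=("A", 34))
        with pytest.raises(Exception, match="OG"):
            triad_geometry(scaffold40, bad)


class TestEnergyWindow:
    @pytest.mark.parametrize("energy, expected", [
        (-2.78, True),   # the template's own docking energy sits in-window
        (-4.5, False),
        (0.5, False),
        (-4.0, True),    # inclusive boundaries
        (0.0, True),
    ])
    def test_window(self, energy, expected):
        assert energy_window_filter(energy, (-4.0, 0.0)) is expected

    def test_bad_window(self):
        with pytest.raises(ValueError):
            energy_window_filter(-1.0, (0.0, -4.0))


class TestAudit:
    def test_full_audit_passes_on_good_geometry(self, scaffold40, triad40):
        pose = make_pose_at_distance(scaffold40, triad40, 3.0, seed=7,
                                     binding_energy=-2.78)
        result = audit_active_site(scaffold40, triad40, pose, min_donors=0)
        assert result.passes["attack_distance"]
        assert result.passes["triad_hbonds"]
        assert result.passes["energy_window"]

    def test_flags_recompute_from_stored_values(self, scaffold40, triad40):
        pose = make_pose_at_distance(scaffold40, triad40, 3.5, seed=8,
                                     binding_energy=-1.0)
        result = audit_active_site(scaffold40, triad40, pose, min_donors=0)
        assert result.passes["attack_distance"] == (result.attack_distance < 4.0)

    def test_rigid_motion_invariance(self, scaffold40, triad40):
        pose = make_pose_at_distance(scaffold40, triad40, 3.2, seed=9)
        # one shared rigid motion applied to both the model and the pose
        from conftest import random_rotation
        rng3 = np.random.default_rng(99)
        R = random_rotation(rng3)
        t = rng3.uniform(-20, 20, 3)
        from rescaffold.fixtures import _copy_model
        mm = _copy_model(scaffold40)
        for res in mm.residues:
            for a in res.atoms:
                a.coords = R @ a.coords + t
        moved_pose = LigandPose(
            atoms=[(lab, el, R @ xyz + t) for lab, el, xyz in pose.atoms],
            ester_groups=pose.ester_groups)
        d0 = attack_distance(scaffold40, triad40, pose)
        d1 = attack_distance(mm, triad40, moved_pose)
        assert d1 == pytest.approx(d0, abs=1e-8)
        g0 = triad_geometry(scaffold40, triad40)
        g1 = triad_geometry(mm, triad40)
        assert g1["ser_OG_his_NE2"] == pytest.approx(g0["ser_OG_his_NE2"],
                                                     abs=1e-8)


class TestPoseTable:
    def test_ester_auto_annotation_matches_hand_annotation(self):
        atoms = [(lab, el, np.asarray(xyz)) for lab, el, xyz in _ESTER_TEMPLATE]
        groups = annotate_ester_groups(atoms)
        # by construction: C1 carbonyl carbon, O1 carbonyl oxygen, O2 ester oxygen
        assert groups == [(0, 1, 2)]

    def test_three_pose_table_sorted_by_energy(self, tmp_path, scaffold40,
                                               triad40):
        energies = [-0.5, -3.1, -2.0]
        lines = ["pose_id\tenergy_kcal_mol\tligand_pdb_path"]
        for k, e in enumerate(energies):
            pose = make_pose_at_distance(scaffold40, triad40, 3.0 + 0.2 * k,
                                         seed=20 + k)
            _write_pose(pose, tmp_path / f"pose{k}.pdb")
            lines.append(f"p{k}\t{e}\tpose{k}.pdb")
        table = tmp_path / "poses.tsv"
        table.write_text("\n".join(lines) + "\n")
        poses = parse_pose_table(table)
        assert [p.binding_energy for p in poses] == sorted(energies)
        assert all(p.ester_groups for p in poses)

    def test_no_carbonyl_warns_and_leaves_empty(self, tmp_path):
        (tmp_path / "flat.pdb").write_text(
            "HETATM    1  C1  LIG A   1       0.000   0.000   0.000"
            "  1.00  0.00           C\n"
            "HETATM    2  C2  LIG A   1       1.500   0.000   0.000"
            "  1.00  0.00           C\n"
            "END\n")
        (tmp_path / "t.tsv").write_text(
            "pose_id\tenergy_kcal_mol\tligand_pdb_path\np0\t-1.0\tflat.pdb\n")
        with pytest.warns(UserWarning):
            poses = parse_pose_table(tmp_path / "t.tsv")
        assert poses[0].ester_groups == []
        # downstream attack_distance must refuse the unannotated pose
        from rescaffold.fixtures import make_toy_scaffold, ToyScaffoldParams
        model = make_toy_scaffold(ToyScaffoldParams(n_residues=20, seed=0))
        with pytest.raises(ValueError):
            attack_distance(model, default_triad(model), poses[0])

    def test_missing_companion_file(self, tmp_path):
        (tmp_path / "t.tsv").write_text(
            "pose_id\tenergy_kcal_mol\tligand_pdb_path\np0\t-1.0\tgone.pdb\n")
        with pytest.raises(FileNotFoundError):
            parse_pose_table(tmp_path / "t.tsv")
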