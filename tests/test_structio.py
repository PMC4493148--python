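"""Structure parsing, preparation rules, torsion trees and pose kinematics."""
import math

import numpy as np
import pytest

from endock import (
    Pose,
    StructureParseError,
    apply_pose,
    detect_metal_ions,
    identity_pose,
    parse_ligand,
    parse_receptor,
    write_poses,
    write_receptor,
)
from endock.structio import read_pose_coords, read_pose_scores


class TestReceptorPreparation:
    def test_waters_removed_and_counted(self, three_res_pdb):
        receptor = parse_receptor(three_res_pdb)
        assert receptor.removed.waters == 2
        assert all(a.residue_name not in ("HOH", "WAT") for a in receptor.atoms)

    def test_hetero_ligand_stripped_and_returned(self, three_res_pdb):
        receptor, stripped = parse_receptor(three_res_pdb, return_stripped=True)
        assert receptor.removed.hetero_ligand_atoms == 2
        assert receptor.removed.hetero_ligand_groups == 1
        (group,) = stripped.values()
        assert {a.name for a in group} == {"C1", "C2"}

    def test_metal_kept_and_detected(self, zinc_pdb):
        receptor = parse_receptor(zinc_pdb)
        metals = detect_metal_ions(receptor)
        assert len(metals) == 1
        assert metals[0].element == "Zn"

    def test_metal_free_structure(self, three_res_pdb):
        assert detect_metal_ions(parse_receptor(three_res_pdb)) == []

    def test_two_metals_by_element(self, mg_ca_pdb):
        metals = detect_metal_ions(parse_receptor(mg_ca_pdb))
        assert {m.element for m in metals} == {"Mg", "Ca"}

    def test_round_trip_pdbqt(self, three_res_pdb, tmp_path):
        receptor = parse_receptor(three_res_pdb)
        out = tmp_path / "prep.pdbqt"
        write_receptor(receptor, out)
        again = parse_receptor(out)
        assert len(again.atoms) == len(receptor.atoms)
        for a, b in zip(receptor.atoms, again.atoms):
            assert a.name == b.name
            assert a.residue_name == b.residue_name
            assert a.residue_number == b.residue_number
            assert np.allclose(a.coords, b.coords, atol=1e-3)

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            parse_receptor("/nonexistent/file.pdb")

    def test_malformed_pdbqt_reports_line(self, tmp_path):
        p = tmp_path / "bad.pdbqt"
        p.write_text("ATOM      1  C1  UNL A   1   badbadbad\n")
        with pytest.raises(StructureParseError, match="bad.pdbqt:1"):
            parse_receptor(p)


class TestLigandParsing:
    def test_rigid_ligand(self, rigid_ligand_pdbqt):
        topo = parse_ligand(rigid_ligand_pdbqt)
        assert topo.n_torsions == 0
        assert topo.torsdof == 0
        assert topo.n_atoms == 3
        assert topo.root_atom_indices == [0, 1, 2]

    def test_nested_branches(self, nested_branch_pdbqt):
        topo = parse_ligand(nested_branch_pdbqt)
        assert topo.n_torsions == 2
        outer, inner = topo.branches
        # inner subtree is strictly contained in the outer subtree
        assert set(inner.subtree) < set(outer.subtree)

    def test_branch_count_matches_torsions(self, nested_branch_pdbqt):
        topo = parse_ligand(nested_branch_pdbqt)
        assert topo.n_torsions == len(topo.branches) == topo.torsdof

    def test_butane_mol2_single_rotatable_bond(self, butane_mol2):
        topo = parse_ligand(butane_mol2)
        # terminal methyl rotations move no heavy atoms: only C2-C3 counts
        assert topo.n_torsions == 1

    def test_unclosed_branch_is_error(self, tmp_path):
        p = tmp_path / "open.pdbqt"
        p.write_text(
            "ROOT\n"
            "ATOM      1  C1  UNL A   1       0.000   0.000   0.000"
            "  1.00  0.00     0.000 C \n"
            "ENDROOT\n"
            "BRANCH   1   2\n"
            "ATOM      2  C2  UNL A   1       1.500   0.000   0.000"
            "  1.00  0.00     0.000 C \n"
        )
        with pytest.raises(StructureParseError, match="unclosed"):
            parse_ligand(p)

    def test_unknown_atom_type_is_error(self, tmp_path):
        p = tmp_path / "unk.pdbqt"
        p.write_text(
            "ROOT\n"
            "ATOM      1  X1  UNL A   1       0.000   0.000   0.000"
            "  1.00  0.00     0.000 XX\n"
            "ENDROOT\n"
        )
        with pytest.raises(StructureParseError, match="XX"):
            parse_ligand(p)


def _rodrigues(v, axis, angle):
    """Independent rotation oracle for the torsion kinematics."""
    k = axis / np.linalg.norm(axis)
    return (
        v * math.cos(angle)
        + np.cross(k, v) * math.sin(angle)
        + k * np.dot(k, v) * (1 - math.cos(angle))
    )


class TestApplyPose:
    def test_identity_is_identity(self, nested_branch_pdbqt):
        topo = parse_ligand(nested_branch_pdbqt)
        pose = identity_pose(topo)
        assert np.allclose(pose.coords, topo.ref_coords, atol=1e-12)

    def test_pure_translation(self, nested_branch_pdbqt):
        topo = parse_ligand(nested_branch_pdbqt)
        t = np.array([1.0, -2.0, 3.5])
        coords = apply_pose(
            topo,
            topo.root_origin() + t,
            np.array([0.0, 0.0, 0.0, 1.0]),
            np.zeros(topo.n_torsions),
        )
        assert np.allclose(coords, topo.ref_coords + t, atol=1e-12)

    def test_torsion_matches_hand_rodrigues(self, nested_branch_pdbqt):
        topo = parse_ligand(nested_branch_pdbqt)
        angle = math.pi
        coords = apply_pose(
            topo,
            topo.root_origin(),
            np.array([0.0, 0.0, 0.0, 1.0]),
            np.array([angle, 0.0]),
        )
        outer = topo.branches[0]
        a = topo.ref_coords[outer.parent]
        axis = topo.ref_coords[outer.child] - a
        for i in outer.subtree:
            expected = _rodrigues(topo.ref_coords[i] - a, axis, angle) + a
            assert np.allclose(coords[i], expected, atol=1e-6)
        # atoms outside the branch are untouched
        untouched = set(range(topo.n_atoms)) - set(outer.subtree)
        for i in untouched:
            assert np.allclose(coords[i], topo.ref_coords[i], atol=1e-12)

    def test_torsion_count_mismatch(self, nested_branch_pdbqt):
        topo = parse_ligand(nested_branch_pdbqt)
        with pytest.raises(ValueError, match="torsions"):
            apply_pose(
                topo, topo.root_origin(), np.array([0.0, 0.0, 0.0, 1.0]), [0.1]
            )

    def test_non_unit_quaternion_rejected(self, nested_branch_pdbqt):
        topo = parse_ligand(nested_branch_pdbqt)
        with pytest.raises(ValueError, match="unit norm"):
            Pose(
                topo,
                position=np.zeros(3),
                orientation=np.array([0.0, 0.0, 0.0, 1.1]),
                torsions=np.zeros(2),
            )


class TestPoseIO:
    def test_write_read_round_trip(self, nested_branch_pdbqt, tmp_path):
        topo = parse_ligand(nested_branch_pdbqt)
        pose = identity_pose(topo)
        pose.score = -10.02
        out = tmp_path / "pose.pdbqt"
        write_poses([pose], out)
        again = parse_ligand(out)
        assert again.n_torsions == topo.n_torsions
        assert np.allclose(again.ref_coords, pose.coords, atol=1e-3)
        assert read_pose_scores(out) == [-10.02]

    def test_nine_models_ascending(self, nested_branch_pdbqt, tmp_path):
        topo = parse_ligand(nested_branch_pdbqt)
        poses = []
        for k in range(9):
            p = identity_pose(topo)
            p.score = -9.0 + 0.5 * k
            poses.append(p)
        out = tmp_path / "nine.pdbqt"
        write_poses(poses, out)
        text = out.read_text()
        assert text.count("MODEL") == 9
        scores = read_pose_scores(out)
        assert scores == sorted(scores)
        assert len(read_pose_coords(out)) == 9
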