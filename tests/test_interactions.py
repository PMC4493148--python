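"""Geometric contact detection with constructed geometries."""
import dataclasses
import json

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from endock import detect_cation_pi, detect_hbonds, detect_hydrophobic, report
from endock.interactions import report_to_json
from endock.structio import Atom, LigandTopology, Pose, Receptor, _flags_from_type


def _atom(serial, name, element, ad_type, xyz, resname="ALA", resnum=1,
          backbone=False, charge=0.0):
    a = Atom(serial=serial, name=name, element=element,
             coords=np.asarray(xyz, dtype=float), ad_type=ad_type,
             residue_name=resname, residue_number=resnum,
             is_backbone=backbone, partial_charge=charge)
    _flags_from_type(a)
    return a


def _ligand_pose(atoms, bonds=()):
    topo = LigandTopology(
        compound_id="LIG",
        atoms=atoms,
        ref_coords=np.array([a.coords for a in atoms]),
        root_atom_indices=list(range(len(atoms))),
        branches=[],
        bonds=list(bonds),
    )
    return Pose(topo, _coords=topo.ref_coords.copy())


def _benzene_atoms(center, start_serial=1):
    atoms = []
    for k in range(6):
        ang = 2 * np.pi * k / 6
        xyz = np.asarray(center) + 1.39 * np.array(
            [np.cos(ang), np.sin(ang), 0.0]
        )
        atoms.append(_atom(start_serial + k, f"C{k+1}", "C", "A", xyz,
                           resname="UNL"))
    bonds = [(k, (k + 1) % 6) for k in range(6)]
    return atoms, bonds


class TestHbonds:
    def test_donor_acceptor_within_cutoff(self):
        receptor = Receptor("r", [
            _atom(1, "O", "O", "OA", [0, 0, 0], resname="ILE", resnum=10,
                  backbone=True),
        ])
        pose = _ligand_pose([_atom(1, "N1", "N", "N", [2.9, 0, 0],
                                   resname="UNL")])
        contacts = detect_hbonds(receptor, pose)
        assert len(contacts) == 1
        c = contacts[0]
        assert c.distance == pytest.approx(2.9)
        assert c.residue == "Ile10"
        assert c.label == "backbone oxygen of Ile10"

    def test_beyond_cutoff_empty(self):
        receptor = Receptor("r", [_atom(1, "O", "O", "OA", [0, 0, 0])])
        pose = _ligand_pose([_atom(1, "N1", "N", "N", [5.0, 0, 0])])
        assert detect_hbonds(receptor, pose) == []

    def test_two_acceptors_give_two_contacts(self):
        receptor = Receptor("r", [
            _atom(1, "O", "O", "OA", [0, 0, 3.0], resname="LEU", resnum=83,
                  backbone=True),
            _atom(2, "O", "O", "OA", [0, 0, -3.0], resname="HIS", resnum=84,
                  backbone=True),
        ])
        pose = _ligand_pose([_atom(1, "N1", "N", "N", [0, 0, 0])])
        contacts = detect_hbonds(receptor, pose)
        assert len(contacts) == 2
        assert {c.residue for c in contacts} == {"Leu83", "His84"}

    def test_apolar_pairs_ignored(self):
        receptor = Receptor("r", [_atom(1, "CB", "C", "C", [0, 0, 0])])
        pose = _ligand_pose([_atom(1, "C1", "C", "C", [3.0, 0, 0])])
        assert detect_hbonds(receptor, pose) == []


class TestHydrophobic:
    def test_contact_labeled_with_residue(self):
        receptor = Receptor("r", [
            _atom(1, "CD1", "C", "C", [0, 0, 0], resname="LEU", resnum=134),
        ])
        pose = _ligand_pose([_atom(1, "C1", "C", "C", [4.0, 0, 0],
                                   resname="UNL")])
        contacts = detect_hydrophobic(receptor, pose)
        assert len(contacts) == 1
        assert contacts[0].residue == "Leu134"
        assert contacts[0].distance == pytest.approx(4.0)

    def test_polar_environment_empty(self):
        receptor = Receptor("r", [
            _atom(1, "OG", "O", "OA", [0, 0, 0], resname="SER"),
        ])
        pose = _ligand_pose([_atom(1, "N1", "N", "N", [3.5, 0, 0])])
        assert detect_hydrophobic(receptor, pose) == []

    def test_same_residue_aggregated_to_min_distance(self):
        receptor = Receptor("r", [
            _atom(1, "CD1", "C", "C", [4.0, 0, 0], resname="ILE", resnum=10),
            _atom(2, "CD2", "C", "C", [4.4, 0, 0], resname="ILE", resnum=10),
        ])
        pose = _ligand_pose([_atom(1, "C1", "C", "C", [0, 0, 0])])
        contacts = detect_hydrophobic(receptor, pose)
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(4.0)


class TestCationPi:
    def test_lysine_over_ligand_ring(self):
        atoms, bonds = _benzene_atoms([0, 0, 0])
        pose = _ligand_pose(atoms, bonds)
        receptor = Receptor("r", [
            _atom(1, "NZ", "N", "N", [0, 0, 4.5], resname="LYS", resnum=33),
        ])
        contacts = detect_cation_pi(receptor, pose)
        assert len(contacts) == 1
        assert contacts[0].residue == "Lys33"
        assert contacts[0].distance == pytest.approx(4.5)

    def test_beyond_cutoff_empty(self):
        atoms, bonds = _benzene_atoms([0, 0, 0])
        pose = _ligand_pose(atoms, bonds)
        receptor = Receptor("r", [
            _atom(1, "NZ", "N", "N", [0, 0, 7.5], resname="LYS", resnum=33),
        ])
        assert detect_cation_pi(receptor, pose) == []

    def test_no_ring_no_cation_empty(self):
        receptor = Receptor("r", [_atom(1, "CB", "C", "C", [0, 0, 0])])
        pose = _ligand_pose([_atom(1, "C1", "C", "C", [3.0, 0, 0])])
        assert detect_cation_pi(receptor, pose) == []

    def test_ligand_cation_vs_receptor_ring(self):
        ring_names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
        atoms = []
        for k, name in enumerate(ring_names):
            ang = 2 * np.pi * k / 6
            atoms.append(_atom(k + 1, name, "C", "A",
                               1.39 * np.array([np.cos(ang), np.sin(ang), 0]),
                               resname="PHE", resnum=80))
        receptor = Receptor("r", atoms)
        lig = _atom(1, "N1", "N", "N", [0, 0, 5.0], charge=1.0)
        lig.charged_positive = True
        pose = _ligand_pose([lig])
        contacts = detect_cation_pi(receptor, pose)
        assert len(contacts) == 1
        assert contacts[0].residue == "Phe80"


class TestReport:
    def _complex_with_one_of_each(self):
        ring_atoms, bonds = _benzene_atoms([0, 0, 0])
        polar = _atom(7, "N7", "N", "N", [5.0, 0, 0], resname="UNL")
        apolar = _atom(8, "C8", "C", "C", [-5.0, 0, 0], resname="UNL")
        pose = _ligand_pose(ring_atoms + [polar, apolar], bonds)
        receptor = Receptor("r", [
            _atom(1, "O", "O", "OA", [7.9, 0, 0], resname="LEU", resnum=83,
                  backbone=True),
            _atom(2, "CD1", "C", "C", [-9.0, 0, 0], resname="ILE", resnum=10),
            _atom(3, "NZ", "N", "N", [0, 0, 4.5], resname="LYS", resnum=33),
        ])
        return receptor, pose

    def test_empty_complex_three_empty_sections(self):
        receptor = Receptor("r", [_atom(1, "CB", "C", "C", [100, 100, 100])])
        pose = _ligand_pose([_atom(1, "C1", "C", "C", [0, 0, 0])])
        rep = report(receptor, pose)
        assert rep["hbond"] == []
        assert rep["hydrophobic"] == []
        assert rep["cation_pi"] == []

    def test_one_contact_of_each_kind(self):
        receptor, pose = self._complex_with_one_of_each()
        rep = report(receptor, pose)
        assert len(rep["hbond"]) == 1
        assert len(rep["hydrophobic"]) == 1
        assert len(rep["cation_pi"]) == 1

    def test_json_round_trip(self):
        receptor, pose = self._complex_with_one_of_each()
        rep = report(receptor, pose)
        assert json.loads(report_to_json(rep)) == rep

    def test_rigid_transform_invariance(self):
        receptor, pose = self._complex_with_one_of_each()
        before = report(receptor, pose)
        rot = Rotation.from_rotvec([0.4, 0.9, -0.2])
        shift = np.array([3.0, -1.0, 7.0])
        moved_receptor = Receptor(receptor.structure_id, [
            dataclasses.replace(a, coords=rot.apply(a.coords) + shift)
            for a in receptor.atoms
        ])
        moved_pose = Pose(pose.topology,
                          _coords=rot.apply(pose.coords) + shift)
        after = report(moved_receptor, moved_pose)
        for kind in ("hbond", "hydrophobic", "cation_pi"):
            assert len(after[kind]) == len(before[kind])
            for a, b in zip(after[kind], before[kind]):
                assert a["distance"] == pytest.approx(b["distance"], abs=1e-3)
                assert a["residue"] == b["residue"]

    def test_distances_within_cutoffs(self):
        receptor, pose = self._complex_with_one_of_each()
        rep = report(receptor, pose)
        cutoffs = {"hbond": 3.5, "hydrophobic": 4.5, "cation_pi": 6.0}
        for kind, cutoff in cutoffs.items():
            for c in rep[kind]:
                assert 0 < c["distance"] <= cutoff
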