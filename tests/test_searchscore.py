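"""Search-box construction, pair terms, direct scoring and grid maps."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import endock
from endock import (
    Box,
    GridMaps,
    box_from_ligand,
    build_grids,
    grid_score,
    pair_energy,
    score_pose,
)
from endock.docking import random_pose
from endock.searchscore import DEFAULT_PARAMS, term_values, vdw_radius
from endock.structio import Atom, Pose, Receptor
from endock.fixtures import FixtureSpec, make_ligand, make_pocket


class TestBox:
    def test_single_atom(self):
        box = box_from_ligand([[1.0, 2.0, 3.0]])
        assert np.allclose(box.center, [1, 2, 3])
        assert np.allclose(box.edge, [10, 10, 10])

    def test_two_atoms_forced_by_definition(self):
        box = box_from_ligand([[0, 0, 0], [4, 6, 2]])
        assert np.allclose(box.center, [2, 3, 1])
        assert np.allclose(box.edge, [16, 16, 16])

    def test_side_mode_doubles_extension(self):
        box = box_from_ligand([[0, 0, 0], [4, 6, 2]], extension=10, mode="side")
        assert np.allclose(box.edge, [26, 26, 26])

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            box_from_ligand(np.empty((0, 3)))

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_cube_contains_all_points(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 5, size=(rng.integers(1, 40), 3))
        box = box_from_ligand(pts)
        assert box.edge[0] == box.edge[1] == box.edge[2]
        assert box.contains(pts).all()
        extent = (pts.max(axis=0) - pts.min(axis=0)).max()
        assert math.isclose(box.edge[0], extent + 10.0, rel_tol=1e-12)

    def test_zero_extension_gives_minimal_cube(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 4, size=(15, 3))
        box = box_from_ligand(pts, extension=0.0)
        extent = (pts.max(axis=0) - pts.min(axis=0)).max()
        assert math.isclose(box.edge[0], extent, rel_tol=1e-12)

    def test_vina_dialect_round_trip(self):
        box = box_from_ligand([[0, 0, 0], [4, 6, 2]])
        again = Box.from_dict(box.to_dict())
        assert np.allclose(again.center, box.center)
        assert np.allclose(again.edge, box.edge)


class TestPairEnergy:
    def test_gauss1_at_contact(self):
        # surface distance zero: unweighted gauss1 = e^0 = 1
        t = term_values(np.array(0.0))
        assert t["gauss1"] == pytest.approx(1.0)

    def test_gauss1_closed_form_at_half_angstrom(self):
        t = term_values(np.array(0.5))
        assert t["gauss1"] == pytest.approx(math.exp(-1.0), abs=1e-12)

    def test_zero_beyond_cutoff(self):
        r = vdw_radius("C") * 2 + 8.0 + 0.01
        assert pair_energy("C", "C", r) == 0.0

    def test_continuity_in_distance(self):
        rs = np.linspace(2.0, 13.0, 4000)
        es = pair_energy("C", "OA", rs)
        assert np.max(np.abs(np.diff(es))) < 0.02

    def test_negative_distance_is_error(self):
        with pytest.raises(ValueError):
            pair_energy("C", "C", -0.1)

    def test_unknown_type_is_error(self):
        with pytest.raises(KeyError):
            pair_energy("ZZ", "C", 3.0)

    def test_hbond_term_only_for_donor_acceptor(self):
        r = vdw_radius("N") + vdw_radius("OA") - 0.7
        e_pair = pair_energy("N", "OA", r)
        e_cc = pair_energy("C", "C", vdw_radius("C") * 2 - 0.7)
        # the donor-acceptor pair gains the full hbond weight
        assert e_pair < e_cc - 0.3


def _one_atom_receptor(ad_type="C", xyz=(0.0, 0.0, 0.0)):
    atom = Atom(serial=1, name="CB", element="C", coords=np.array(xyz),
                ad_type=ad_type, residue_name="ALA", residue_number=1)
    return Receptor("single", [atom])


def _one_atom_ligand(ad_type="C"):
    text = (
        "ROOT\n"
        f"ATOM      1  C1  UNL A   1       0.000   0.000   0.000"
        f"  1.00  0.00     0.000 {ad_type:<2}\n"
        "ENDROOT\nTORSDOF 0\n"
    )
    import tempfile, os
    from endock import parse_ligand

    with tempfile.NamedTemporaryFile("w", suffix=".pdbqt", delete=False) as fh:
        fh.write(text)
        path = fh.name
    try:
        return parse_ligand(path)
    finally:
        os.unlink(path)


class TestScorePose:
    def test_isolated_ligand_scores_zero(self, small_ligand):
        receptor = _one_atom_receptor(xyz=(500.0, 500.0, 500.0))
        pose = endock.identity_pose(small_ligand)
        sb = score_pose(receptor, pose)
        assert sb.inter == 0.0
        assert sb.normalized == 0.0

    def test_single_pair_equals_pair_energy(self):
        receptor = _one_atom_receptor()
        topo = _one_atom_ligand()
        for r in (3.2, 3.8, 4.4, 6.0):
            pose = Pose(
                topo,
                position=np.array([r, 0.0, 0.0]),
                orientation=np.array([0.0, 0.0, 0.0, 1.0]),
                torsions=np.zeros(0),
            )
            sb = score_pose(receptor, pose)
            assert sb.inter == pytest.approx(pair_energy("C", "C", r), abs=1e-12)
            assert sb.normalized == pytest.approx(sb.inter, abs=1e-12)

    def test_rigid_transform_invariance(self, flexible_case):
        from scipy.spatial.transform import Rotation

        receptor = flexible_case.receptor
        pose = flexible_case.crystal_pose
        before = score_pose(receptor, pose).inter
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7])
        shift = np.array([5.0, -3.0, 2.0])
        moved_atoms = []
        for a in receptor.atoms:
            import dataclasses

            b = dataclasses.replace(a, coords=rot.apply(a.coords) + shift)
            moved_atoms.append(b)
        moved_receptor = Receptor(receptor.structure_id, moved_atoms)
        moved_pose = Pose(
            pose.topology, _coords=rot.apply(pose.coords) + shift
        )
        after = score_pose(moved_receptor, moved_pose).inter
        assert after == pytest.approx(before, abs=1e-9)

    def test_boundary_penalty_outside_box(self):
        receptor = _one_atom_receptor(xyz=(500.0, 500.0, 500.0))
        topo = _one_atom_ligand()
        box = Box(center=[0, 0, 0], edge=[10, 10, 10])
        pose = Pose(
            topo, position=np.array([7.0, 0.0, 0.0]),
            orientation=np.array([0.0, 0.0, 0.0, 1.0]), torsions=np.zeros(0),
        )
        sb = score_pose(receptor, pose, box=box)
        assert sb.inter == pytest.approx(DEFAULT_PARAMS.boundary_k * 2.0**2)


class TestGrids:
    def test_node_value_equals_direct_sum(self, rigid_case):
        receptor = rigid_case.receptor
        box = box_from_ligand(rigid_case.crystal_pose.coords)
        grids = build_grids(receptor, box, spacing=0.5, ligand_types={"C"})
        # probe a lattice node directly
        i, j, k = 3, 4, 5
        node = grids.origin + np.array([i, j, k]) * grids.spacing
        direct = 0.0
        for a in receptor.heavy_atoms():
            r = float(np.linalg.norm(a.coords - node))
            direct += pair_energy("C", a.ad_type, r)
        vals, outside = grids.interpolate("C", node[None, :])
        assert not outside.any()
        assert vals[0] == pytest.approx(direct, abs=1e-9)

    def test_empty_receptor_gives_zero_maps(self):
        receptor = _one_atom_receptor(xyz=(999.0, 999.0, 999.0))
        box = Box(center=[0, 0, 0], edge=[8, 8, 8])
        grids = build_grids(receptor, box, spacing=0.5, ligand_types={"C", "OA"})
        for m in grids.maps.values():
            assert np.all(m == 0.0)

    def test_midpoint_is_mean_of_adjacent_nodes(self):
        # handcrafted map: interpolation at an edge midpoint is linear
        box = Box(center=[0, 0, 0], edge=[2, 2, 2])
        dims = (5, 5, 5)
        rng = np.random.default_rng(0)
        grid = rng.normal(size=dims)
        gm = GridMaps(box=box, spacing=0.5, origin=box.lower, dims=dims,
                      maps={"C": grid})
        p0 = box.lower + np.array([1.0, 1.0, 1.0]) * 0.5
        p1 = box.lower + np.array([2.0, 1.0, 1.0]) * 0.5
        mid = (p0 + p1) / 2
        vals, _ = gm.interpolate("C", np.stack([p0, p1, mid]))
        assert vals[2] == pytest.approx((vals[0] + vals[1]) / 2, abs=1e-12)

    def test_memory_budget_error_advises_coarser_spacing(self, rigid_case):
        receptor = rigid_case.receptor
        box = box_from_ligand(rigid_case.crystal_pose.coords)
        with pytest.raises(MemoryError, match="coarser"):
            build_grids(receptor, box, spacing=0.01, ligand_types={"C"},
                        memory_budget_bytes=10_000_000)

    def test_missing_map_type_is_error(self, rigid_case):
        receptor = rigid_case.receptor
        box = box_from_ligand(rigid_case.crystal_pose.coords)
        grids = build_grids(receptor, box, spacing=0.5, ligand_types={"C"})
        with pytest.raises(KeyError):
            grids.interpolate("OA", np.zeros((1, 3)))

    def test_save_load_round_trip(self, rigid_case, tmp_path):
        receptor = rigid_case.receptor
        box = box_from_ligand(rigid_case.crystal_pose.coords)
        grids = build_grids(receptor, box, spacing=0.5, ligand_types={"C", "N"})
        path = tmp_path / "grids.npz"
        grids.save(path)
        again = GridMaps.load(path)
        assert again.spacing == grids.spacing
        assert again.dims == grids.dims
        for t in grids.maps:
            assert np.array_equal(again.maps[t], grids.maps[t])

    def test_grid_matches_direct_scoring(self, flexible_case):
        """Oracle equivalence: interpolated inter-energy tracks the direct
        pair sum on random non-clashing poses."""
        receptor = flexible_case.receptor
        topo = flexible_case.topology
        box = box_from_ligand(flexible_case.crystal_pose.coords)
        types = {a.ad_type for a in topo.atoms if a.is_heavy}
        grids = build_grids(receptor, box, spacing=0.25, ligand_types=types)
        lo, hi = grids.origin, grids.domain_upper
        rng = np.random.default_rng(7)
        n_heavy = len(topo.heavy_indices())
        checked = 0
        while checked < 100:
            pose = random_pose(topo, box, rng)
            if not np.all((pose.coords >= lo) & (pose.coords <= hi)):
                continue
            direct = score_pose(receptor, pose, box=box)
            if direct.inter > 0:
                continue  # clash region: fidelity contract is the smooth region
            approx = grid_score(grids, pose)
            assert abs(approx.inter - direct.inter) / n_heavy <= 0.05
            checked += 1
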