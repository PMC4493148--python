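"""Deterministic synthetic receptors, ligands and redocking cases.

These fixtures are physically naive by design: no real chemistry, just
geometry chosen so that the scoring minimum is known.  A fixture ligand is a
zigzag heavy-atom chain (optionally ending in an aromatic six-ring) with a
chosen number of rotatable bonds; a fixture pocket is a cage of receptor
atoms placed at near-ideal contact distances around an embedded ligand
conformation, which makes the embedded pose the energy minimum and gives
redocking runs an exact ground truth — something real crystal structures
cannot provide at unit-test scale.  Outputs are byte-reproducible from the
seed and always pass the package's own parsers.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .searchscore import (
    DEFAULT_PARAMS,
    ScoringParams,
    box_from_ligand,
    score_pose,
    vdw_radius,
)
from .structio import (
    Atom,
    LigandTopology,
    Pose,
    Receptor,
    StructureParseError,
    format_pdbqt_atom,
    write_receptor,
    write_poses,
)

_BOND = 1.5          # chain bond length, Angstrom
_ZIG = math.radians(35.25)  # half the zigzag turn: 109.5 deg bond angles
_RING_BOND = 1.39


@dataclass
class FixtureSpec:
    seed: int = 0
    # ligand
    heavy_atoms: int = 10
    torsions: int = 3
    aromatic: bool = False
    cationic: bool = False       # add a positively charged ligand nitrogen
    n_polar: int = 3             # donor/acceptor substitutions along the chain
    compound_id: str = "FIX00000001"
    # pocket
    pocket_atoms: int = 40
    pocket_radius: float = 6.0
    polar_fraction: float = 0.25
    structure_id: str = "fixp"
    # redock-case construction
    contacts_per_atom: int = 6
    anchors_per_polar: int = 2   # h-bond anchor atoms per polar ligand atom
    embed_jitter: float = 1.0    # max |offset| of the embedded root, Angstrom


# ---------------------------------------------------------------------------
# Ligand
# ---------------------------------------------------------------------------


def _chain_coords(n: int) -> np.ndarray:
    """Planar zigzag chain with tetrahedral-like bond angles."""
    coords = np.zeros((n, 3))
    for i in range(1, n):
        theta = _ZIG if i % 2 else -_ZIG
        coords[i] = coords[i - 1] + _BOND * np.array(
            [math.cos(theta), math.sin(theta), 0.0]
        )
    return coords


def _ligand_pdbqt_text(spec: FixtureSpec) -> str:
    n = spec.heavy_atoms
    if n < 1:
        raise ValueError("ligand needs at least one heavy atom")
    if spec.torsions > max(n - 3, 0):
        raise ValueError(
            f"cannot place {spec.torsions} rotatable bonds on a "
            f"{n}-heavy-atom chain"
        )
    coords = _chain_coords(n)
    # atom types: mostly carbon; polar substitutions at the head end break
    # the end-to-end symmetry of the chain
    ad_types = ["C"] * n
    # polar substitutions at every other position from the head end; the
    # donor/acceptor alternation makes the chain strongly asymmetric
    polar_cycle = ["N", "OA", "NA", "OA", "N"]
    placed = 0
    for k in range(0, n - 1, 2):
        if placed >= spec.n_polar:
            break
        ad_types[k] = polar_cycle[placed % len(polar_cycle)]
        placed += 1
    ring_atoms: list[tuple[str, np.ndarray]] = []
    if spec.aromatic:
        # hexagon fused to the tail atom, in the chain plane
        tail = coords[-1]
        direction = coords[-1] - coords[-2]
        direction = direction / np.linalg.norm(direction)
        center = tail + direction * (_BOND + _RING_BOND)
        for k in range(6):
            ang = 2 * math.pi * k / 6
            # ring plane spanned by chain direction and z
            offset = _RING_BOND * (
                math.cos(ang) * direction + math.sin(ang) * np.array([0, 0, 1.0])
            )
            ring_atoms.append(("A", center + offset))
    charges = [0.0] * n
    if spec.cationic and ad_types[0] == "N":
        charges[0] = 1.0
    # rotatable bonds: interior chain bonds, evenly spaced, never touching
    # the terminal atoms (terminal rotations move nothing heavy)
    if spec.torsions:
        cut_positions = np.linspace(1, n - 3, spec.torsions)
        cuts = sorted({int(round(p)) for p in cut_positions})
        while len(cuts) < spec.torsions:  # collisions at tiny n
            for c in range(1, n - 2):
                if c not in cuts:
                    cuts.append(c)
                    break
            cuts.sort()
    else:
        cuts = []
    # segments: [0..cuts[0]], [cuts[0]+1..cuts[1]], ..., tail gets the ring
    lines = ["ROOT"]
    serial = 0
    all_atoms: list[str] = []

    def atom_line(ad: str, xyz: np.ndarray, charge: float) -> str:
        nonlocal serial
        serial += 1
        elem = {"A": "C", "NA": "N", "OA": "O", "SA": "S"}.get(ad, ad)
        a = Atom(
            serial=serial,
            name=f"{elem}{serial}",
            element=elem,
            coords=xyz,
            partial_charge=charge,
            ad_type=ad,
            residue_name="UNL",
            residue_number=1,
            chain="A",
        )
        return format_pdbqt_atom(a)

    seg_ends = cuts + [n - 1]
    start = 0
    open_branches = []
    for si, end in enumerate(seg_ends):
        if si > 0:
            lines.append(f"BRANCH {start:>3} {start + 1:>3}")
            open_branches.append((start, start + 1))
        for i in range(start, end + 1):
            lines.append(atom_line(ad_types[i], coords[i], charges[i]))
        if si == len(seg_ends) - 1:
            for ad, xyz in ring_atoms:
                lines.append(atom_line(ad, xyz, 0.0))
        if si == 0:
            lines.append("ENDROOT")
        start = end + 1
    for p, c in reversed(open_branches):
        lines.append(f"ENDBRANCH {p:>3} {c:>3}")
    lines.append(f"TORSDOF {len(cuts)}")
    return "\n".join(lines) + "\n"


def make_ligand(spec: FixtureSpec, path=None) -> LigandTopology:
    """Generate a chain-topology fixture ligand; the emitted PDBQT text is a
    pure function of the spec."""
    from . import structio

    text = _ligand_pdbqt_text(spec)
    import os
    import tempfile

    if path is not None:
        Path(path).write_text(text)
        topo = structio.parse_ligand(path, format="pdbqt")
    else:
        with tempfile.NamedTemporaryFile(
            "w", suffix=".pdbqt", delete=False
        ) as fh:
            fh.write(text)
            tmp = fh.name
        try:
            topo = structio.parse_ligand(tmp, format="pdbqt")
        finally:
            os.unlink(tmp)
    topo.compound_id = spec.compound_id
    return topo


# ---------------------------------------------------------------------------
# Pocket
# ---------------------------------------------------------------------------

# residue disguises for cage atoms, so labels downstream look like a protein
_HYDRO_RES = [("ALA", "CB"), ("LEU", "CD1"), ("ILE", "CD1"), ("VAL", "CG1")]
_ACCEPTOR_RES = [("SER", "OG"), ("THR", "OG1")]
_DONOR_RES = [("ASN", "ND2"), ("GLN", "NE2")]


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = math.pi * (1 + math.sqrt(5)) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def make_pocket(spec: FixtureSpec, path=None) -> Receptor:
    """Spherical cage of receptor atoms around the origin."""
    dirs = _fibonacci_sphere(spec.pocket_atoms)
    rng = np.random.default_rng(spec.seed)
    n_polar = int(round(spec.polar_fraction * spec.pocket_atoms))
    atoms: list[Atom] = []
    for i in range(spec.pocket_atoms):
        polar = i < n_polar
        if polar:
            resname, name = _ACCEPTOR_RES[i % len(_ACCEPTOR_RES)]
            ad, elem = "OA", "O"
        else:
            resname, name = _HYDRO_RES[i % len(_HYDRO_RES)]
            ad, elem = "C", "C"
        atom = Atom(
            serial=i + 1,
            name=name,
            element=elem,
            coords=dirs[i] * spec.pocket_radius,
            ad_type=ad,
            residue_name=resname,
            residue_number=i + 1,
            chain="A",
        )
        from .structio import _flags_from_type

        _flags_from_type(atom)
        atoms.append(atom)
    receptor = Receptor(spec.structure_id, atoms)
    if path is not None:
        write_receptor(receptor, path)
    return receptor


# ---------------------------------------------------------------------------
# Redock case: ligand embedded in a complementary cage
# ---------------------------------------------------------------------------


@dataclass
class RedockCase:
    receptor: Receptor
    crystal_pose: Pose
    topology: LigandTopology
    manifest: dict


def _random_embed(spec: FixtureSpec, topo: LigandTopology, rng) -> Pose:
    position = rng.uniform(-spec.embed_jitter, spec.embed_jitter, 3)
    quat = Rotation.random(random_state=rng).as_quat()
    torsions = rng.uniform(-math.pi, math.pi, topo.n_torsions)
    return Pose(
        topo,
        position=position,
        orientation=quat / np.linalg.norm(quat),
        torsions=torsions,
    )


def _cage_atoms(
    spec: FixtureSpec, topo: LigandTopology, lig_coords: np.ndarray, rng
) -> list[Atom]:
    heavy = topo.heavy_indices()
    center = lig_coords[heavy].mean(axis=0)
    atoms: list[Atom] = []
    serial = 0
    resnum = 0
    for ai in heavy:
        la = topo.atoms[ai]
        polar = la.hbond_donor or la.hbond_acceptor
        n_anchors = spec.anchors_per_polar if polar else 0
        for ci in range(spec.contacts_per_atom):
            want_anchor = ci < n_anchors
            placed = False
            for _try in range(12):
                out = lig_coords[ai] - center
                nrm = np.linalg.norm(out)
                out = out / nrm if nrm > 1e-6 else np.array([0, 0, 1.0])
                jitter = rng.normal(0, 0.45, 3)
                direction = out + jitter
                direction /= np.linalg.norm(direction)
                if want_anchor:
                    ad, elem, gap = ("OA", "O", -0.5) if la.hbond_donor else ("N", "N", -0.5)
                    resname, name = ("SER", "OG") if ad == "OA" else ("ASN", "ND2")
                else:
                    ad, elem, gap = "C", "C", 0.2
                    resname, name = _HYDRO_RES[serial % len(_HYDRO_RES)]
                r_rec = vdw_radius(ad)
                pos = lig_coords[ai] + direction * (
                    vdw_radius(la.ad_type) + r_rec + gap
                )
                # reject placements clashing with, or ambiguously close to,
                # other ligand atoms: the cage atom must contact its partner
                d_all = np.linalg.norm(lig_coords[heavy] - pos, axis=1)
                radii = np.array(
                    [vdw_radius(topo.atoms[j].ad_type) for j in heavy]
                )
                surf = d_all - (radii + r_rec)
                others = np.ones(len(heavy), dtype=bool)
                others[np.where(heavy == ai)[0]] = False
                if np.any(surf[others] < gap + 0.15) or surf.min() < gap - 0.05:
                    continue
                serial += 1
                resnum += 1
                atom = Atom(
                    serial=serial,
                    name=name,
                    element=elem,
                    coords=pos,
                    ad_type=ad,
                    residue_name=resname,
                    residue_number=resnum,
                    chain="A",
                )
                from .structio import _flags_from_type

                _flags_from_type(atom)
                atoms.append(atom)
                placed = True
                break
            if not placed:
                continue  # crowded direction; the cage tolerates gaps
    return atoms


def make_redock_case(
    spec: FixtureSpec, params: ScoringParams = DEFAULT_PARAMS
) -> RedockCase:
    """Ligand embedded at a known pose inside a shape-complementary cage.

    The cage places receptor atoms at near-optimal contact distances around
    the embedded conformation, so the scoring minimum sits at (or very near)
    the embedded pose; construction is verified by direct scoring against
    100 random poses and the seed is perturbed and the build retried if the
    check fails (recorded in the manifest).
    """
    attempt = 0
    while True:
        seed = spec.seed + 1000 * attempt
        rng = np.random.default_rng(seed)
        topo = make_ligand(spec)
        crystal = _random_embed(spec, topo, rng)
        lig_coords = crystal.coords
        atoms = _cage_atoms(spec, topo, lig_coords, rng)
        if len(atoms) >= spec.contacts_per_atom:
            receptor = Receptor(f"{spec.structure_id}{spec.seed:04d}", atoms)
            truth_score = score_pose(receptor, crystal, params).total
            box = box_from_ligand(lig_coords)
            from .docking import random_pose

            rand_best = math.inf
            for _ in range(100):
                rp = random_pose(topo, box, rng)
                rand_best = min(rand_best, score_pose(receptor, rp, params).total)
            decoy_gap = -math.inf
            if truth_score < rand_best and truth_score < 0:
                decoy_gap = _verify_minimum(
                    receptor, crystal, topo, box, params, seed
                )
            if decoy_gap > 0:
                manifest = {
                    "seed": spec.seed,
                    "build_attempts": attempt + 1,
                    "truth_position": crystal.position.tolist(),
                    "truth_orientation": crystal.orientation.tolist(),
                    "truth_torsions": crystal.torsions.tolist(),
                    "truth_score": truth_score,
                    "best_random_score": rand_best,
                    "decoy_energy_gap": decoy_gap,
                    "n_cage_atoms": len(atoms),
                }
                return RedockCase(receptor, crystal, topo, manifest)
        attempt += 1
        if attempt > 20:
            raise StructureParseError(
                f"could not build a valid redock case from seed {spec.seed}"
            )


def _verify_minimum(
    receptor: Receptor,
    crystal: Pose,
    topo: LigandTopology,
    box,
    params: ScoringParams,
    seed: int,
) -> float:
    """Construction check that the embedded pose is the *global* scoring
    minimum: refine the embedded pose and run a short multi-start search on
    the same grid field; returns the energy gap between the best search
    minimum that is conformationally distinct (heavy-atom RMSD >= 2 A from
    the embedded pose) and the refined embedded pose.  Positive gap =
    embedded pose wins and the case is usable as redocking ground truth."""
    from .docking import (
        DockingConfig, _BatchEvaluator, _pack, _unpack,
        pattern_refine_batch, task_rng, _run_tasks,
    )
    from .evaluation import rmsd
    from .searchscore import build_grids

    types = {a.ad_type for a in topo.atoms if a.is_heavy}
    grids = build_grids(
        receptor, box.padded(2.0), spacing=0.4, ligand_types=types,
        params=params,
    )
    energy = _BatchEvaluator(topo, grids, params)
    _, e_truth_arr = pattern_refine_batch(
        _pack(crystal)[None, :], energy, topo.n_torsions
    )
    e_truth = float(e_truth_arr[0])
    cfg = DockingConfig(n_tasks=16, seed=seed + 77, iterations=8)
    rngs = [task_rng(cfg.seed, i) for i in range(cfg.n_tasks)]
    V, E = _run_tasks(topo, grids, cfg, rngs, params)
    crystal_heavy = crystal.heavy_coords
    distinct = [
        float(E[k]) for k in range(len(V))
        if rmsd(_unpack(topo, V[k]).heavy_coords, crystal_heavy) >= 2.0
    ]
    if not distinct:
        return math.inf
    return min(distinct) - e_truth


def study_specs(n_cases: int = 20, base_seed: int = 0) -> list[FixtureSpec]:
    """Specs for a standard synthetic redocking study.

    Cases span the small-ligand envelope the fixtures emulate — rigid
    through flexible: torsion counts cycle 0..3 and heavy-atom counts cycle
    8..12 across the set, so the study covers rigid, mildly flexible and
    fully flexible compounds in equal measure.
    """
    specs = []
    for k in range(n_cases):
        specs.append(
            FixtureSpec(
                seed=base_seed + k,
                heavy_atoms=8 + k % 5,
                torsions=k % 4,
                compound_id=f"FIX{base_seed + k:08d}",
                structure_id="fixp",
            )
        )
    return specs


def write_case(case: RedockCase, out_dir) -> dict:
    """Emit receptor/ligand/crystal PDBQT files plus a manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    receptor_path = out / f"{case.receptor.structure_id}.pdbqt"
    ligand_path = out / f"{case.topology.compound_id}.pdbqt"
    crystal_path = out / f"{case.topology.compound_id}_crystal.pdbqt"
    write_receptor(case.receptor, receptor_path)
    ligand_path.write_text(
        _ligand_text_from_topology(case.topology)
    )
    write_poses([case.crystal_pose], crystal_path)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(case.manifest, indent=1, sort_keys=True))
    return {
        "receptor": str(receptor_path),
        "ligand": str(ligand_path),
        "crystal": str(crystal_path),
        "manifest": str(manifest_path),
    }


def _ligand_text_from_topology(topo: LigandTopology) -> str:
    lines = []
    for item in topo.layout:
        kind = item[0]
        if kind == "ATOM":
            lines.append(format_pdbqt_atom(topo.atoms[item[1]]))
        elif kind == "ROOT":
            lines.append("ROOT")
        elif kind == "ENDROOT":
            lines.append("ENDROOT")
        elif kind == "BRANCH":
            lines.append(f"BRANCH {item[1]:>3} {item[2]:>3}")
        elif kind == "ENDBRANCH":
            lines.append(f"ENDBRANCH {item[1]:>3} {item[2]:>3}")
        elif kind == "TORSDOF":
            lines.append(f"TORSDOF {item[1]}")
    return "\n".join(lines) + "\n"
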