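"""Structure I/O: PDB/PDBQT/Mol2 reading and writing, atom typing, torsion trees.

PDBQT is the canonical internal format.  Receptors are prepared by stripping
waters and non-metal hetero groups (metal ions are kept so that structures
containing them can be detected and excluded from an ensemble).  Ligands carry
the PDBQT ROOT/BRANCH rotatable-bond tree, and poses are materialized from
(position, orientation, torsions) by forward kinematics over that tree.
"""
from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

log = logging.getLogger("endock")

# ---------------------------------------------------------------------------
# Atom-type tables (AutoDock4/Vina dialect)
# ---------------------------------------------------------------------------

METAL_ELEMENTS = frozenset(
    {"Zn", "Mg", "Mn", "Fe", "Ca", "Na", "K", "Cu", "Ni", "Co", "Cd",
     "Hg", "Sr", "Cs", "Li", "Al"}
)

#: Recognised AutoDock atom types.  ``A`` is aromatic carbon; the ``NA``/
#: ``OA``/``SA`` variants are hydrogen-bond acceptors; ``HD`` is a polar
#: (donor) hydrogen.
AD_TYPES = frozenset(
    {"C", "A", "N", "NA", "O", "OA", "S", "SA", "H", "HD", "P",
     "F", "Cl", "Br", "I"} | METAL_ELEMENTS
)

HYDROPHOBIC_TYPES = frozenset({"C", "A", "F", "Cl", "Br", "I"})
ACCEPTOR_TYPES = frozenset({"NA", "OA", "SA"})
#: Type-level donors: nitrogen that is not an acceptor carries (or can carry)
#: a polar hydrogen; metals coordinate acceptors the way donors do.
DONOR_TYPES = frozenset({"N"}) | METAL_ELEMENTS

AD_TO_ELEMENT = {
    "C": "C", "A": "C", "N": "N", "NA": "N", "O": "O", "OA": "O",
    "S": "S", "SA": "S", "H": "H", "HD": "H", "P": "P",
    "F": "F", "Cl": "Cl", "Br": "Br", "I": "I",
}
AD_TO_ELEMENT.update({m: m for m in METAL_ELEMENTS})

WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})
BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

_AROMATIC_RING_ATOMS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}
#: Receptor aromatic-ring membership for cation-pi detection (ring atom names
#: per residue type; TRP contributes its six-membered ring).
RECEPTOR_RING_TEMPLATES = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TRP": [("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
}
_CATION_ATOMS = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE")}
_ANION_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
# hydroxyl / amide-NH side-chain donors in standard residues
_SIDECHAIN_DONORS = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
    ("ASN", "ND2"), ("GLN", "NE2"), ("TRP", "NE1"),
    ("HIS", "ND1"), ("HIS", "NE2"),
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
}

# single-bond covalent radii, used only for distance-based bond inference
_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}


class StructureParseError(ValueError):
    """Malformed structure file; message carries file and line number."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Atom:
    """A typed heavy atom or hydrogen with its PDB identity."""

    serial: int
    name: str
    element: str
    coords: np.ndarray  # (3,) Angstrom
    partial_charge: float = 0.0
    ad_type: str = "C"
    residue_name: str = "UNL"
    residue_number: int = 1
    chain: str = "A"
    is_backbone: bool = False
    hydrophobic: bool = False
    hbond_donor: bool = False
    hbond_acceptor: bool = False
    charged_positive: bool = False
    charged_negative: bool = False
    aromatic: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.serial}")
        if self.ad_type not in AD_TYPES:
            raise ValueError(f"unknown AutoDock atom type {self.ad_type!r}")

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    @property
    def is_metal(self) -> bool:
        return self.element in METAL_ELEMENTS


def _flags_from_type(atom: Atom) -> None:
    """Derive interaction flags deterministically from ad_type + identity."""
    atom.hydrophobic = atom.ad_type in HYDROPHOBIC_TYPES
    atom.hbond_acceptor = atom.ad_type in ACCEPTOR_TYPES
    atom.hbond_donor = atom.ad_type in DONOR_TYPES
    key = (atom.residue_name, atom.name)
    if key in _SIDECHAIN_DONORS:
        atom.hbond_donor = True
    atom.charged_positive = key in _CATION_ATOMS or atom.is_metal
    atom.charged_negative = key in _ANION_ATOMS
    ring = _AROMATIC_RING_ATOMS.get(atom.residue_name)
    atom.aromatic = atom.ad_type == "A" or bool(ring and atom.name in ring)


@dataclass
class RemovedCounts:
    waters: int = 0
    hetero_ligand_atoms: int = 0
    hetero_ligand_groups: int = 0
    altloc: int = 0


@dataclass
class Receptor:
    """Prepared protein structure: no waters, no non-metal hetero groups."""

    structure_id: str
    atoms: list[Atom]
    removed: RemovedCounts = field(default_factory=RemovedCounts)

    def __post_init__(self) -> None:
        for a in self.atoms:
            if a.residue_name in WATER_RESNAMES:
                raise ValueError("receptor contains water atoms")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms]).reshape(-1, 3)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]


def detect_metal_ions(receptor: Receptor) -> list[Atom]:
    """All atoms whose element belongs to the documented metal set.

    Structures carrying metal ions near the site distort empirical docking
    scores, so ensembles are built from metal-free structures only; this is
    the predicate behind that exclusion rule.
    """
    return [a for a in receptor.atoms if a.is_metal]


# ---------------------------------------------------------------------------
# Ligand topology: the PDBQT ROOT/BRANCH rotatable-bond tree
# ---------------------------------------------------------------------------


@dataclass
class Branch:
    parent: int  # atom index in topology
    child: int
    subtree: np.ndarray  # indices of every atom inside the BRANCH block


@dataclass
class LigandTopology:
    """A compound with reference coordinates and its rotatable-bond tree.

    ``branches`` are stored in file (depth-first) order, parents before
    children, which is the order torsions are applied in.
    """

    compound_id: str
    atoms: list[Atom]
    ref_coords: np.ndarray  # (n, 3)
    root_atom_indices: list[int]
    branches: list[Branch]
    torsdof: int | None = None
    layout: list[tuple] = field(default_factory=list)  # PDBQT record skeleton
    bonds: list[tuple[int, int]] = field(default_factory=list)
    _intra_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.ref_coords = np.asarray(self.ref_coords, dtype=float).reshape(-1, 3)
        if sum(a.is_heavy for a in self.atoms) < 1:
            raise ValueError("ligand must contain at least one heavy atom")

    @property
    def n_torsions(self) -> int:
        return len(self.branches)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.is_heavy], dtype=int)

    def root_origin(self) -> np.ndarray:
        """Reference position of the root frame: the first ROOT atom."""
        return self.ref_coords[self.root_atom_indices[0]]

    def graph_distances(self) -> np.ndarray:
        """All-pairs bond-graph distances (inferred bonds), cached."""
        if "gd" not in self._intra_cache:
            from scipy.sparse import csr_matrix
            from scipy.sparse.csgraph import shortest_path

            n = self.n_atoms
            if self.bonds:
                i, j = zip(*self.bonds)
                data = np.ones(len(self.bonds))
                adj = csr_matrix((data, (i, j)), shape=(n, n))
                adj = adj + adj.T
            else:
                adj = csr_matrix((n, n))
            self._intra_cache["gd"] = shortest_path(adj, unweighted=True)
        return self._intra_cache["gd"]


def infer_bonds(atoms: Sequence[Atom], coords: np.ndarray,
                tolerance: float = 0.45) -> list[tuple[int, int]]:
    """Distance-based covalent bond inference (PDBQT stores no bond table)."""
    n = len(atoms)
    radii = np.array([_COVALENT_RADII.get(a.element, 0.77) for a in atoms])
    bonds: list[tuple[int, int]] = []
    for i in range(n):
        d = np.linalg.norm(coords[i + 1:] - coords[i], axis=1)
        cut = radii[i] + radii[i + 1:] + tolerance
        for k in np.nonzero(d <= cut)[0]:
            bonds.append((i, int(i + 1 + k)))
    return bonds


@dataclass
class Pose:
    """One placed conformation of a ligand.

    Coordinates are a deterministic function of (position, orientation,
    torsions); a pose read back from a file may carry explicit coordinates
    instead.
    """

    topology: LigandTopology
    position: np.ndarray | None = None
    orientation: np.ndarray | None = None  # unit quaternion, scipy [x,y,z,w]
    torsions: np.ndarray | None = None
    score: float = math.nan
    _coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.orientation is not None:
            self.orientation = np.asarray(self.orientation, dtype=float)
            if abs(np.linalg.norm(self.orientation) - 1.0) > 1e-9:
                raise ValueError("orientation quaternion must have unit norm")
        if self.position is not None:
            self.position = np.asarray(self.position, dtype=float)
        if self.torsions is not None:
            self.torsions = np.asarray(self.torsions, dtype=float)

    @property
    def coords(self) -> np.ndarray:
        if self._coords is None:
            self._coords = apply_pose(
                self.topology, self.position, self.orientation, self.torsions
            )
        return self._coords

    @property
    def heavy_coords(self) -> np.ndarray:
        return self.coords[self.topology.heavy_indices()]


def identity_pose(topology: LigandTopology) -> Pose:
    """The pose whose coordinates equal the reference coordinates."""
    return Pose(
        topology,
        position=topology.root_origin().copy(),
        orientation=np.array([0.0, 0.0, 0.0, 1.0]),
        torsions=np.zeros(topology.n_torsions),
    )


def apply_pose(
    topology: LigandTopology,
    position: np.ndarray,
    orientation: np.ndarray,
    torsions: Sequence[float],
) -> np.ndarray:
    """Forward kinematics of the torsion tree.

    Torsions rotate each BRANCH subtree about its parent->child bond axis in
    depth-first order, then the whole molecule is rigidly rotated about the
    root-frame origin and translated so the origin lands on ``position``.
    """
    torsions = np.asarray(torsions, dtype=float)
    if torsions.shape[0] != topology.n_torsions:
        raise ValueError(
            f"expected {topology.n_torsions} torsions, got {torsions.shape[0]}"
        )
    coords = topology.ref_coords.copy()
    for branch, angle in zip(topology.branches, torsions):
        a = coords[branch.parent]
        axis = coords[branch.child] - a
        nrm = np.linalg.norm(axis)
        if nrm < 1e-9:
            raise ValueError("degenerate rotatable bond (zero length)")
        k = axis / nrm
        v = coords[branch.subtree] - a
        # Rodrigues rotation about the bond axis
        c, s = math.cos(angle), math.sin(angle)
        coords[branch.subtree] = (
            v * c + np.cross(k, v) * s + np.outer(v @ k, k) * (1.0 - c)
        ) + a
    x, y, z, w = np.asarray(orientation, dtype=float)
    rotm = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    origin = topology.root_origin()
    return (coords - origin) @ rotm.T + np.asarray(position, dtype=float)


def _quat_matrices(quats: np.ndarray) -> np.ndarray:
    """Rotation matrices (K,3,3) from unit quaternions (K,4) in [x,y,z,w]."""
    x, y, z, w = quats[:, 0], quats[:, 1], quats[:, 2], quats[:, 3]
    m = np.empty((len(quats), 3, 3))
    m[:, 0, 0] = 1 - 2 * (y * y + z * z)
    m[:, 0, 1] = 2 * (x * y - z * w)
    m[:, 0, 2] = 2 * (x * z + y * w)
    m[:, 1, 0] = 2 * (x * y + z * w)
    m[:, 1, 1] = 1 - 2 * (x * x + z * z)
    m[:, 1, 2] = 2 * (y * z - x * w)
    m[:, 2, 0] = 2 * (x * z - y * w)
    m[:, 2, 1] = 2 * (y * z + x * w)
    m[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return m


def apply_pose_batch(
    topology: LigandTopology,
    positions: np.ndarray,   # (K, 3)
    orientations: np.ndarray,  # (K, 4) unit quaternions
    torsions: np.ndarray,    # (K, n_torsions)
) -> np.ndarray:
    """Vectorized :func:`apply_pose` over K parameter sets -> (K, n, 3)."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    orientations = np.atleast_2d(np.asarray(orientations, dtype=float))
    torsions = np.asarray(torsions, dtype=float).reshape(len(positions), -1)
    if torsions.shape[1] != topology.n_torsions:
        raise ValueError("torsion count mismatch")
    K = len(positions)
    coords = np.broadcast_to(
        topology.ref_coords, (K,) + topology.ref_coords.shape
    ).copy()
    for b, branch in enumerate(topology.branches):
        a = coords[:, branch.parent]  # (K,3)
        axis = coords[:, branch.child] - a
        axis = axis / np.linalg.norm(axis, axis=1, keepdims=True)
        ang = torsions[:, b]
        c = np.cos(ang)[:, None, None]
        s = np.sin(ang)[:, None, None]
        v = coords[:, branch.subtree] - a[:, None, :]  # (K,m,3)
        kxv = np.cross(axis[:, None, :], v)
        kdv = np.einsum("kj,kmj->km", axis, v)
        coords[:, branch.subtree] = (
            v * c + kxv * s + kdv[:, :, None] * axis[:, None, :] * (1.0 - c)
        ) + a[:, None, :]
    rotm = _quat_matrices(orientations)
    origin = topology.root_origin()
    return np.einsum("kij,knj->kni", rotm, coords - origin) + positions[:, None, :]


# ---------------------------------------------------------------------------
# PDBQT parsing
# ---------------------------------------------------------------------------


def _parse_pdbqt_atom_line(line: str, path: str, lineno: int) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip() or "UNL"
        chain = line[21:22].strip() or "A"
        resnum = int(line[22:26]) if line[22:26].strip() else 1
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        charge_s = line[70:76].strip()
        charge = float(charge_s) if charge_s else 0.0
        ad_type = line[77:79].strip()
    except (ValueError, IndexError) as exc:
        raise StructureParseError(f"{path}:{lineno}: malformed ATOM record: {exc}")
    if not ad_type:
        raise StructureParseError(f"{path}:{lineno}: missing AutoDock atom type")
    if ad_type not in AD_TYPES:
        raise StructureParseError(
            f"{path}:{lineno}: unknown AutoDock atom type {ad_type!r}"
        )
    atom = Atom(
        serial=serial,
        name=name,
        element=AD_TO_ELEMENT[ad_type],
        coords=np.array([x, y, z]),
        partial_charge=charge,
        ad_type=ad_type,
        residue_name=resname,
        residue_number=resnum,
        chain=chain,
        is_backbone=name in BACKBONE_ATOM_NAMES,
    )
    _flags_from_type(atom)
    return atom


def format_pdbqt_atom(atom: Atom, record: str = "ATOM") -> str:
    name = atom.name
    # PDB name justification: element symbols of one letter start in col 14
    name_f = f" {name:<3}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4}"
    return (
        f"{record:<6}{atom.serial:>5} {name_f}"
        f" {atom.residue_name:>3} {atom.chain:1}{atom.residue_number:>4}    "
        f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}    {atom.partial_charge:6.3f} {atom.ad_type:<2}"
    )


def _parse_receptor_pdbqt(path: Path, structure_id: str) -> Receptor:
    atoms: list[Atom] = []
    removed = RemovedCounts()
    het_groups: set[tuple] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            altloc = line[16:17].strip()
            if altloc not in ("", "A"):
                removed.altloc += 1
                continue
            atom = _parse_pdbqt_atom_line(line, str(path), lineno)
            if atom.residue_name in WATER_RESNAMES:
                removed.waters += 1
                continue
            if rec == "HETATM" and not atom.is_metal:
                removed.hetero_ligand_atoms += 1
                het_groups.add((atom.chain, atom.residue_number, atom.residue_name))
                continue
            atoms.append(atom)
    removed.hetero_ligand_groups = len(het_groups)
    if not atoms:
        raise StructureParseError(f"{path}: no atoms after preparation")
    return Receptor(structure_id, atoms, removed)


def assign_receptor_ad_type(element: str, name: str, resname: str) -> str:
    """AutoDock type for a receptor atom from its element and PDB identity."""
    if element == "C":
        ring = _AROMATIC_RING_ATOMS.get(resname)
        return "A" if ring and name in ring else "C"
    if element == "N":
        # imidazole nitrogens accept; all other protein N are donors
        if (resname, name) in {("HIS", "ND1"), ("HIS", "NE2")}:
            return "NA"
        return "N"
    if element == "O":
        return "OA"
    if element == "S":
        return "SA" if resname == "CYS" else "S"
    if element == "H":
        return "H"
    if element in METAL_ELEMENTS:
        return element
    if element in AD_TYPES:
        return element
    raise ValueError(f"cannot type element {element!r} ({resname} {name})")


def _parse_receptor_pdb(path: Path, structure_id: str) -> tuple[Receptor, dict]:
    import gemmi

    st = gemmi.read_structure(str(path))
    atoms: list[Atom] = []
    removed = RemovedCounts()
    stripped: dict[tuple, list[Atom]] = {}
    model = st[0]
    serial = 0
    for chain in model:
        for res in chain:
            is_water = res.is_water() or res.name in WATER_RESNAMES
            is_het = res.het_flag == "H"
            for at in res:
                if at.altloc not in ("\0", "", "A"):
                    removed.altloc += 1
                    continue
                elem = at.element.name
                if is_water:
                    removed.waters += 1
                    continue
                serial += 1
                if is_het and elem not in METAL_ELEMENTS and not is_water:
                    removed.hetero_ligand_atoms += 1
                    atom = Atom(
                        serial=serial, name=at.name, element=elem,
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        ad_type=_het_ad_type(elem),
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        chain=chain.name,
                    )
                    _flags_from_type(atom)
                    stripped.setdefault(
                        (chain.name, res.seqid.num, res.name), []
                    ).append(atom)
                    continue
                atom = Atom(
                    serial=serial, name=at.name, element=elem,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    ad_type=assign_receptor_ad_type(elem, at.name, res.name),
                    residue_name=res.name,
                    residue_number=res.seqid.num,
                    chain=chain.name,
                    is_backbone=at.name in BACKBONE_ATOM_NAMES,
                )
                _flags_from_type(atom)
                atoms.append(atom)
    removed.hetero_ligand_groups = len(stripped)
    if not atoms:
        raise StructureParseError(f"{path}: no atoms after preparation")
    return Receptor(structure_id, atoms, removed), stripped


def _het_ad_type(element: str) -> str:
    return {"C": "C", "N": "NA", "O": "OA", "S": "SA", "H": "H"}.get(
        element, element if element in AD_TYPES else "C"
    )


def parse_receptor(path, format: str | None = None, return_stripped: bool = False):
    """Read and prepare a receptor structure.

    Waters and non-metal HETATM groups are removed (counts recorded); metal
    ions are retained so :func:`detect_metal_ions` can flag the structure.
    With ``return_stripped=True`` the stripped hetero groups are returned as
    a second value keyed by (chain, residue number, residue name).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("pdbqt" if path.suffix.lower() == ".pdbqt" else "pdb")
    structure_id = path.stem
    if fmt == "pdbqt":
        receptor = _parse_receptor_pdbqt(path, structure_id)
        stripped: dict = {}
    elif fmt == "pdb":
        receptor, stripped = _parse_receptor_pdb(path, structure_id)
    else:
        raise ValueError(f"unsupported receptor format {fmt!r}")
    if receptor.removed.waters:
        log.info("%s: removed %d water atoms", path, receptor.removed.waters)
    if receptor.removed.hetero_ligand_atoms:
        log.info(
            "%s: stripped %d hetero atoms in %d groups",
            path, receptor.removed.hetero_ligand_atoms,
            receptor.removed.hetero_ligand_groups,
        )
    if return_stripped:
        return receptor, stripped
    return receptor


def write_receptor(receptor: Receptor, path) -> None:
    """Write a prepared receptor as PDBQT."""
    lines = [format_pdbqt_atom(a) for a in receptor.atoms]
    Path(path).write_text("\n".join(lines) + "\nTER\n")


# ---------------------------------------------------------------------------
# Ligand PDBQT parsing (ROOT / BRANCH / TORSDOF)
# ---------------------------------------------------------------------------


def _parse_ligand_pdbqt(path: Path, compound_id: str) -> LigandTopology:
    atoms: list[Atom] = []
    layout: list[tuple] = []
    serial_to_index: dict[int, int] = {}
    branch_stack: list[tuple[int, int, int]] = []  # (parent_serial, child_serial, start)
    branches_raw: list[tuple[int, int, list[int]]] = []
    torsdof: int | None = None
    in_model = 0
    seen_root = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line[:6].strip().upper()
            where = f"{path}:{lineno}"
            if rec == "MODEL":
                in_model += 1
                if in_model > 1:
                    break  # topology comes from the first model
            elif rec == "ENDMDL":
                break
            elif rec == "ROOT":
                if seen_root:
                    raise StructureParseError(f"{where}: duplicate ROOT")
                seen_root = True
                layout.append(("ROOT",))
            elif rec == "ENDROO":  # ENDROOT truncated to 6 chars
                layout.append(("ENDROOT",))
            elif rec == "BRANCH":
                try:
                    p, c = (int(t) for t in line.split()[1:3])
                except (ValueError, IndexError):
                    raise StructureParseError(f"{where}: malformed BRANCH record")
                if p not in serial_to_index:
                    raise StructureParseError(
                        f"{where}: BRANCH parent {p} not yet defined"
                    )
                branch_stack.append((p, c, len(atoms)))
                layout.append(("BRANCH", p, c))
            elif rec == "ENDBRA":  # ENDBRANCH
                if not branch_stack:
                    raise StructureParseError(f"{where}: unmatched ENDBRANCH")
                p, c, start = branch_stack.pop()
                if c not in serial_to_index:
                    raise StructureParseError(
                        f"{where}: BRANCH child {c} has no atom record"
                    )
                branches_raw.append((p, c, list(range(start, len(atoms)))))
                layout.append(("ENDBRANCH", p, c))
            elif rec == "TORSDO":  # TORSDOF
                torsdof = int(line.split()[1])
                layout.append(("TORSDOF", torsdof))
            elif rec in ("ATOM", "HETATM"):
                atom = _parse_pdbqt_atom_line(line, str(path), lineno)
                if atom.serial in serial_to_index:
                    raise StructureParseError(
                        f"{where}: duplicate atom serial {atom.serial}"
                    )
                serial_to_index[atom.serial] = len(atoms)
                layout.append(("ATOM", len(atoms)))
                atoms.append(atom)
    if branch_stack:
        raise StructureParseError(f"{path}: unclosed BRANCH block")
    if not atoms:
        raise StructureParseError(f"{path}: no atoms")
    coords = np.array([a.coords for a in atoms])
    # branches in file order of their BRANCH statement (outer before nested)
    order = {(p, c): i for i, (p, c) in enumerate(
        (item[1], item[2]) for item in layout if item[0] == "BRANCH"
    )}
    branches_raw.sort(key=lambda b: order[(b[0], b[1])])
    branches = [
        Branch(serial_to_index[p], serial_to_index[c], np.array(sub, dtype=int))
        for p, c, sub in branches_raw
    ]
    if seen_root and ("ENDROOT",) in layout:
        head = layout[: layout.index(("ENDROOT",))]
        root_indices = [item[1] for item in head if item[0] == "ATOM"]
    else:
        root_indices = list(range(len(atoms)))
    if not root_indices:
        raise StructureParseError(f"{path}: empty ROOT block")
    topo = LigandTopology(
        compound_id=compound_id,
        atoms=atoms,
        ref_coords=coords,
        root_atom_indices=root_indices,
        branches=branches,
        torsdof=torsdof,
        layout=layout,
        bonds=infer_bonds(atoms, coords),
    )
    if torsdof is not None and torsdof != topo.n_torsions:
        log.warning(
            "%s: TORSDOF %d != %d BRANCH records", path, torsdof, topo.n_torsions
        )
    return topo


def _parse_ligand_mol2(path: Path, compound_id: str) -> LigandTopology:
    """Mol2 ingest via RDKit: perceive rotatable bonds, build a torsion tree."""
    from rdkit import Chem

    mol = Chem.MolFromMol2File(str(path), sanitize=True, removeHs=False)
    if mol is None:
        raise StructureParseError(f"{path}: RDKit could not parse Mol2 file")
    return topology_from_rdkit(mol, compound_id)


_ROTATABLE_SMARTS = "[!$(*#*)&!D1]-&!@[!$(*#*)&!D1]"


def topology_from_rdkit(mol, compound_id: str) -> LigandTopology:
    from rdkit import Chem

    conf = mol.GetConformer()
    coords = np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
          conf.GetAtomPosition(i).z] for i in range(mol.GetNumAtoms())]
    )
    atoms: list[Atom] = []
    for i, a in enumerate(mol.GetAtoms()):
        elem = a.GetSymbol()
        if elem == "C":
            ad = "A" if a.GetIsAromatic() else "C"
        elif elem == "N":
            has_h = a.GetTotalNumHs(includeNeighbors=True) > 0
            ad = "N" if has_h else "NA"
        elif elem == "O":
            ad = "OA"
        elif elem == "S":
            ad = "SA"
        elif elem == "H":
            nb = a.GetNeighbors()
            ad = "HD" if nb and nb[0].GetSymbol() in ("N", "O", "S") else "H"
        else:
            ad = elem if elem in AD_TYPES else "C"
        atom = Atom(
            serial=i + 1, name=f"{elem}{i + 1}", element=elem,
            coords=coords[i], ad_type=ad,
            partial_charge=a.GetDoubleProp("_TriposPartialCharge")
            if a.HasProp("_TriposPartialCharge") else 0.0,
        )
        _flags_from_type(atom)
        if a.GetFormalCharge() > 0:
            atom.charged_positive = True
        elif a.GetFormalCharge() < 0:
            atom.charged_negative = True
        atoms.append(atom)
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    patt = Chem.MolFromSmarts(_ROTATABLE_SMARTS)
    rot_pairs = {tuple(sorted(m)) for m in mol.GetSubstructMatches(patt)}
    return _build_tree(compound_id, atoms, coords, bonds, rot_pairs)


def _build_tree(
    compound_id: str,
    atoms: list[Atom],
    coords: np.ndarray,
    bonds: list[tuple[int, int]],
    rotatable: set[tuple[int, int]],
) -> LigandTopology:
    """Build a ROOT/BRANCH tree by cutting rotatable bonds; root = largest
    rigid fragment (ties broken by lowest original atom index)."""
    import networkx as nx

    g_rigid = nx.Graph()
    g_rigid.add_nodes_from(range(len(atoms)))
    g_rigid.add_edges_from(
        e for e in bonds if tuple(sorted(e)) not in rotatable
    )
    frags = [sorted(c) for c in nx.connected_components(g_rigid)]
    frags.sort(key=lambda f: (-sum(atoms[i].is_heavy for i in f), f[0]))
    frag_of = {i: k for k, f in enumerate(frags) for i in f}
    # fragment adjacency through rotatable bonds: child frag -> (parent atom, child atom)
    adj: dict[int, list[tuple[int, int, int]]] = {k: [] for k in range(len(frags))}
    for i, j in rotatable:
        fi, fj = frag_of[i], frag_of[j]
        if fi != fj:
            adj[fi].append((fj, i, j))
            adj[fj].append((fi, j, i))

    new_index: dict[int, int] = {}
    seq: list[int] = []
    layout: list[tuple] = [("ROOT",)]
    branch_spans: list[tuple[int, int, int, int]] = []  # parent_old, child_old, start, end
    visited = {0}

    def emit_frag(fk: int) -> None:
        for i in frags[fk]:
            new_index[i] = len(seq)
            layout.append(("ATOM", len(seq)))
            seq.append(i)
        if fk == 0:
            layout.append(("ENDROOT",))
        for fj, a_parent, a_child in sorted(adj[fk]):
            if fj in visited:
                continue
            visited.add(fj)
            layout.append(("BRANCH*", a_parent, a_child))
            start = len(seq)
            emit_frag(fj)
            branch_spans.append((a_parent, a_child, start, len(seq)))
            layout.append(("ENDBRANCH*", a_parent, a_child))

    emit_frag(0)
    if len(seq) < len(atoms):
        raise StructureParseError(
            f"{compound_id}: rotatable-bond graph is not a tree"
        )
    layout.append(("TORSDOF", len(branch_spans)))
    new_atoms = [atoms[i] for i in seq]
    for k, a in enumerate(new_atoms):
        a.serial = k + 1
    fixed_layout = [
        (item[0].rstrip("*"), new_index[item[1]] + 1, new_index[item[2]] + 1)
        if item[0] in ("BRANCH*", "ENDBRANCH*") else item
        for item in layout
    ]
    branches = [
        Branch(new_index[p], new_index[c], np.arange(start, end))
        for p, c, start, end in branch_spans
    ]
    branch_order = {
        (item[1] - 1, item[2] - 1): k
        for k, item in enumerate(i for i in fixed_layout if i[0] == "BRANCH")
    }
    branches.sort(key=lambda b: branch_order[(b.parent, b.child)])
    return LigandTopology(
        compound_id=compound_id,
        atoms=new_atoms,
        ref_coords=coords[seq],
        root_atom_indices=[new_index[i] for i in frags[0]],
        branches=branches,
        torsdof=len(branches),
        layout=fixed_layout,
        bonds=[(new_index[i], new_index[j]) for i, j in bonds],
    )


def parse_ligand(path, format: str | None = None) -> LigandTopology:
    """Read a ligand and its rotatable-bond tree from PDBQT or Mol2."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or path.suffix.lower().lstrip(".")
    if fmt == "pdbqt":
        return _parse_ligand_pdbqt(path, path.stem)
    if fmt == "mol2":
        return _parse_ligand_mol2(path, path.stem)
    raise ValueError(f"unsupported ligand format {fmt!r}")


# ---------------------------------------------------------------------------
# Pose writing
# ---------------------------------------------------------------------------

_SCORE_RE = re.compile(r"REMARK\s+SCORE\s+(-?\d+(?:\.\d+)?)")


def _pose_block(pose: Pose, model: int) -> list[str]:
    topo = pose.topology
    coords = pose.coords
    lines = [f"MODEL {model:>8}"]
    if not math.isnan(pose.score):
        lines.append(f"REMARK SCORE {pose.score:.2f}")
    layout = topo.layout or (
        [("ROOT",)] + [("ATOM", i) for i in range(topo.n_atoms)]
        + [("ENDROOT",), ("TORSDOF", 0)]
    )
    for item in layout:
        kind = item[0]
        if kind == "ATOM":
            a = topo.atoms[item[1]]
            saved = a.coords
            a.coords = coords[item[1]]
            lines.append(format_pdbqt_atom(a))
            a.coords = saved
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
    lines.append("ENDMDL")
    return lines


def write_pose(pose: Pose, path) -> None:
    write_poses([pose], path)


def write_poses(poses: Sequence[Pose], path) -> None:
    """Write poses as a multi-MODEL PDBQT, scores recorded as REMARK SCORE."""
    lines: list[str] = []
    for m, pose in enumerate(poses, 1):
        lines.extend(_pose_block(pose, m))
    Path(path).write_text("\n".join(lines) + "\n")


def read_pose_scores(path) -> list[float]:
    """Scores recorded in the REMARK SCORE lines of a multi-MODEL PDBQT."""
    return [float(m.group(1)) for m in _SCORE_RE.finditer(Path(path).read_text())]


def read_pose_coords(path) -> list[np.ndarray]:
    """Per-MODEL coordinate arrays from a multi-MODEL ligand PDBQT."""
    models: list[np.ndarray] = []
    current: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip().upper()
            if rec == "MODEL":
                current = []
            elif rec == "ENDMDL":
                models.append(np.array(current))
            elif rec in ("ATOM", "HETATM"):
                current.append(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
    if not models and current:
        models.append(np.array(current))
    return models
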