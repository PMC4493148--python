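"""Geometric protein-ligand interaction detection with residue labels.

Three contact kinds are reported for a receptor-pose complex: hydrogen bonds
(donor/acceptor heavy-atom pairs within 3.5 A), hydrophobic contacts
(apolar heavy-atom pairs within 4.5 A, aggregated per residue), and cation-pi
interactions (cationic center to aromatic-ring centroid within 6.0 A, both
directions).  Cutoffs follow common interaction-fingerprint practice and are
all configurable; no angular criteria are applied by default.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .structio import Atom, Pose, Receptor, RECEPTOR_RING_TEMPLATES

_ELEMENT_WORDS = {
    "O": "oxygen", "N": "nitrogen", "C": "carbon", "S": "sulfur",
    "H": "hydrogen", "P": "phosphorus", "F": "fluorine",
    "Cl": "chlorine", "Br": "bromine", "I": "iodine",
}


def _residue_label(atom: Atom) -> str:
    part = "backbone" if atom.is_backbone else "side-chain"
    elem = _ELEMENT_WORDS.get(atom.element, atom.element)
    res = atom.residue_name.capitalize()
    return f"{part} {elem} of {res}{atom.residue_number}"


@dataclass
class Contact:
    kind: str  # hbond | hydrophobic | cation_pi
    ligand_atom: str  # ligand atom name
    partner: str  # receptor atom name or ring descriptor
    residue: str  # e.g. "Leu83"
    distance: float
    label: str

    def to_dict(self) -> dict:
        return asdict(self)


def detect_hbonds(
    receptor: Receptor, pose: Pose, d_max: float = 3.5
) -> list[Contact]:
    """Donor/acceptor heavy-atom pairs within the cutoff, one contact per
    pair (both polarities: ligand donor vs receptor acceptor and vice versa).
    """
    contacts: list[Contact] = []
    coords = pose.coords
    lig = pose.topology.atoms
    for i, la in enumerate(lig):
        if not la.is_heavy or not (la.hbond_donor or la.hbond_acceptor):
            continue
        for ra in receptor.atoms:
            if not ra.is_heavy:
                continue
            pair_ok = (la.hbond_donor and ra.hbond_acceptor) or (
                la.hbond_acceptor and ra.hbond_donor
            )
            if not pair_ok:
                continue
            d = float(np.linalg.norm(coords[i] - ra.coords))
            if 0.0 < d <= d_max:
                contacts.append(
                    Contact(
                        kind="hbond",
                        ligand_atom=la.name,
                        partner=ra.name,
                        residue=f"{ra.residue_name.capitalize()}{ra.residue_number}",
                        distance=round(d, 3),
                        label=_residue_label(ra),
                    )
                )
    return contacts


def detect_hydrophobic(
    receptor: Receptor, pose: Pose, d_max: float = 4.5
) -> list[Contact]:
    """Hydrophobic heavy-atom pairs within the cutoff, aggregated to one
    contact per (ligand atom, residue) at the minimum distance."""
    best: dict[tuple[int, tuple], tuple[float, Atom]] = {}
    coords = pose.coords
    for i, la in enumerate(pose.topology.atoms):
        if not la.is_heavy or not la.hydrophobic:
            continue
        for ra in receptor.atoms:
            if not ra.is_heavy or not ra.hydrophobic:
                continue
            d = float(np.linalg.norm(coords[i] - ra.coords))
            if not (0.0 < d <= d_max):
                continue
            key = (i, (ra.chain, ra.residue_number, ra.residue_name))
            if key not in best or d < best[key][0]:
                best[key] = (d, ra)
    contacts = []
    for (i, _), (d, ra) in sorted(best.items()):
        la = pose.topology.atoms[i]
        contacts.append(
            Contact(
                kind="hydrophobic",
                ligand_atom=la.name,
                partner=ra.name,
                residue=f"{ra.residue_name.capitalize()}{ra.residue_number}",
                distance=round(d, 3),
                label=_residue_label(ra),
            )
        )
    return contacts


def _ligand_rings(pose: Pose) -> list[tuple[str, np.ndarray]]:
    """Aromatic 5/6-membered rings of the ligand as (descriptor, centroid)."""
    import networkx as nx

    topo = pose.topology
    if not topo.bonds:
        return []
    g = nx.Graph(topo.bonds)
    g.add_nodes_from(range(topo.n_atoms))
    coords = pose.coords
    rings = []
    for cycle in nx.cycle_basis(g):
        if len(cycle) not in (5, 6):
            continue
        if not all(topo.atoms[i].aromatic for i in cycle):
            continue
        centroid = coords[list(cycle)].mean(axis=0)
        names = "-".join(topo.atoms[i].name for i in sorted(cycle))
        rings.append((f"ring[{names}]", centroid))
    return rings


def _receptor_rings(receptor: Receptor) -> list[tuple[str, str, np.ndarray]]:
    """Aromatic side-chain rings as (descriptor, residue, centroid)."""
    import logging

    log = logging.getLogger("endock")
    by_res: dict[tuple, dict[str, Atom]] = {}
    for a in receptor.atoms:
        if a.residue_name in RECEPTOR_RING_TEMPLATES:
            by_res.setdefault(
                (a.chain, a.residue_number, a.residue_name), {}
            )[a.name] = a
    rings = []
    for (chain, num, resname), atoms in sorted(by_res.items()):
        for template in RECEPTOR_RING_TEMPLATES[resname]:
            members = [atoms.get(n) for n in template]
            if any(m is None for m in members):
                log.warning(
                    "ring perception: %s%s missing ring atoms, skipped",
                    resname, num,
                )
                continue
            centroid = np.mean([m.coords for m in members], axis=0)
            rings.append((f"{resname.capitalize()}{num} ring", f"{resname.capitalize()}{num}", centroid))
    return rings


def detect_cation_pi(
    receptor: Receptor, pose: Pose, d_max: float = 6.0
) -> list[Contact]:
    """Cationic-center to aromatic-ring-centroid pairs within the cutoff,
    checked in both directions."""
    contacts: list[Contact] = []
    coords = pose.coords
    # receptor cation vs ligand ring
    lig_rings = _ligand_rings(pose)
    for ra in receptor.atoms:
        if not ra.charged_positive:
            continue
        for desc, centroid in lig_rings:
            d = float(np.linalg.norm(ra.coords - centroid))
            if 0.0 < d <= d_max:
                contacts.append(
                    Contact(
                        kind="cation_pi",
                        ligand_atom=desc,
                        partner=ra.name,
                        residue=f"{ra.residue_name.capitalize()}{ra.residue_number}",
                        distance=round(d, 3),
                        label=_residue_label(ra),
                    )
                )
    # ligand cation vs receptor ring
    rec_rings = _receptor_rings(receptor)
    for i, la in enumerate(pose.topology.atoms):
        if not la.charged_positive:
            continue
        for desc, residue, centroid in rec_rings:
            d = float(np.linalg.norm(coords[i] - centroid))
            if 0.0 < d <= d_max:
                contacts.append(
                    Contact(
                        kind="cation_pi",
                        ligand_atom=la.name,
                        partner=desc,
                        residue=residue,
                        distance=round(d, 3),
                        label=f"aromatic ring of {residue}",
                    )
                )
    return contacts


def report(
    receptor: Receptor,
    pose: Pose,
    hbond_cutoff: float = 3.5,
    hydrophobic_cutoff: float = 4.5,
    cation_pi_cutoff: float = 6.0,
) -> dict:
    """Run all three detectors and group contacts by kind."""
    return {
        "compound_id": pose.topology.compound_id,
        "structure_id": receptor.structure_id,
        "hbond": [c.to_dict() for c in detect_hbonds(receptor, pose, hbond_cutoff)],
        "hydrophobic": [
            c.to_dict() for c in detect_hydrophobic(receptor, pose, hydrophobic_cutoff)
        ],
        "cation_pi": [
            c.to_dict() for c in detect_cation_pi(receptor, pose, cation_pi_cutoff)
        ],
    }


def report_to_json(rep: dict) -> str:
    return json.dumps(rep, indent=1, sort_keys=True)
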