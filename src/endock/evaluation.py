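"""Redocking accuracy: fixed-order heavy-atom RMSD, RMSD1/RMSDm, 2 A counts.

RMSD is computed in the shared docking frame with no superposition and no
graph-symmetry correction; "pose 1" is the best-scoring pose, "pose m" the
pose of minimum RMSD among the (at most nine) returned poses, so
RMSDm <= RMSD1 holds by construction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .docking import DockingConfig, dock
from .searchscore import DEFAULT_PARAMS, ScoringParams, box_from_ligand
from .structio import LigandTopology, Pose, Receptor


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Root-mean-square deviation between two equal-length, identically
    ordered coordinate sets (Angstrom, no superposition)."""
    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    if len(a) == 0:
        raise ValueError("empty coordinate set")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


@dataclass
class RedockRecord:
    structure_id: str
    pose_rmsds: list[float]  # by ascending-score pose order
    rmsd1: float = math.nan
    rmsdm: float = math.nan
    pose_scores: list[float] = field(default_factory=list)
    failed: bool = False

    def __post_init__(self) -> None:
        if self.pose_rmsds:
            self.rmsd1 = self.pose_rmsds[0]
            self.rmsdm = min(self.pose_rmsds)
            assert self.rmsdm <= self.rmsd1
        else:
            self.failed = True


def redock_evaluate(
    complexes: list[tuple[Receptor, Pose, LigandTopology]],
    config: DockingConfig = DockingConfig(),
    params: ScoringParams = DEFAULT_PARAMS,
    box_extension: float = 10.0,
) -> list[RedockRecord]:
    """Dock each crystal ligand back into its own receptor and record the
    RMSD of every returned pose to the crystal conformation.

    Each complex is (receptor, crystal pose, ligand topology); the search box
    is derived from the crystal ligand the way production runs derive it.
    """
    records: list[RedockRecord] = []
    for receptor, crystal, topology in complexes:
        crystal_heavy = crystal.heavy_coords
        box = box_from_ligand(crystal.coords, extension=box_extension)
        result = dock(
            topology, receptor=receptor, box=box, config=config, params=params
        )
        if not result.ok:
            records.append(RedockRecord(receptor.structure_id, []))
            continue
        rmsds = [rmsd(p.heavy_coords, crystal_heavy) for p in result.poses]
        records.append(
            RedockRecord(
                receptor.structure_id,
                rmsds,
                pose_scores=[p.score for p in result.poses],
            )
        )
    return records


def success_counts(
    records: list[RedockRecord], threshold: float = 2.0
) -> tuple[int, int]:
    """(count of RMSD1 < threshold, count of RMSDm < threshold), strict."""
    ok = [r for r in records if not r.failed]
    n1 = sum(r.rmsd1 < threshold for r in ok)
    nm = sum(r.rmsdm < threshold for r in ok)
    return n1, nm


def records_to_rows(records: list[RedockRecord]) -> list[dict]:
    """Long-format rows (structure, pose number, score, RMSD) for CSV export."""
    rows = []
    for r in records:
        for k, val in enumerate(r.pose_rmsds, 1):
            score = r.pose_scores[k - 1] if k <= len(r.pose_scores) else math.nan
            rows.append(
                {
                    "structure_id": r.structure_id,
                    "pose": k,
                    "score": score,
                    "rmsd": val,
                }
            )
        if r.failed:
            rows.append(
                {
                    "structure_id": r.structure_id,
                    "pose": 0,
                    "score": math.nan,
                    "rmsd": math.nan,
                }
            )
    return rows
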