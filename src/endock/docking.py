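"""Multi-start Monte-Carlo conformational search inside the box.

Each docking run launches ``n_tasks`` independent Metropolis Monte-Carlo
tasks (default 256, mirroring the production setting), each seeded from its
own deterministic RNG stream, pools the per-task minima, removes near-
duplicate conformations, and keeps at most nine poses sorted by score.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
from scipy.spatial.transform import Rotation

from .searchscore import (
    Box,
    DEFAULT_PARAMS,
    GridMaps,
    ScoringParams,
    build_grids,
    intra_energy,
    normalized_score,
)
from .structio import LigandTopology, Pose, Receptor


@dataclass
class DockingConfig:
    n_tasks: int = 256
    max_poses: int = 9
    seed: int = 0
    iterations: int | None = None  # per task; default scales with torsions
    translation_step: float = 1.0  # Angstrom
    rotation_step: float = 1.0     # radians
    torsion_step: float = 1.5      # radians
    reseed_probability: float = 0.25  # hops that redraw orientation+torsions
    rmsd_threshold: float = 2.0    # pose-distinctness, heavy-atom Angstrom
    temperature: float = 1.2       # Metropolis kT, kcal/mol
    polish_hops: int = 8           # small-perturbation polish of kept poses
    grid_spacing: float = 0.25     # used when grids must be built internally
    grid_padding: float = 2.0      # extra margin so the lattice covers the box

    def __post_init__(self) -> None:
        if self.n_tasks < 1:
            raise ValueError("n_tasks must be >= 1")
        if not (1 <= self.max_poses <= 9):
            raise ValueError("max_poses must be between 1 and 9")

    def budget(self, n_torsions: int) -> int:
        """Basin hops per task; each hop spends a local refinement."""
        if self.iterations is not None:
            return self.iterations
        return 6 * (1 + n_torsions)


@dataclass
class DockResult:
    compound_id: str
    structure_id: str
    poses: list[Pose]
    best_score: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return bool(self.poses) and math.isfinite(self.best_score)


def task_rng(seed: int, task_index: int) -> np.random.Generator:
    """Independent per-task RNG stream: deterministic and order-independent."""
    return np.random.default_rng(np.random.SeedSequence((seed, task_index)))


def random_pose(topology: LigandTopology, box: Box, rng: np.random.Generator) -> Pose:
    """Uniform pose: root origin uniform in the box, orientation uniform on
    SO(3), torsions uniform in (-pi, pi]."""
    position = box.lower + rng.random(3) * (box.upper - box.lower)
    orientation = Rotation.random(random_state=rng).as_quat()
    orientation = orientation / np.linalg.norm(orientation)
    torsions = math.pi - rng.random(topology.n_torsions) * (2 * math.pi)
    return Pose(topology, position=position, orientation=orientation, torsions=torsions)


def _draw_position(box: Box, rng: np.random.Generator) -> np.ndarray:
    """Search-start position: half uniform over the box, half concentrated
    near its center.  The box is constructed around the bound-ligand site,
    so its center is the natural prior for where poses bind."""
    if rng.random() < 0.5:
        return box.lower + rng.random(3) * (box.upper - box.lower)
    pos = box.center + rng.normal(0.0, box.edge / 8)
    return np.clip(pos, box.lower, box.upper)


# ---------------------------------------------------------------------------
# Internal parameter-vector representation: [tx,ty,tz, qx,qy,qz,qw, torsions]
# ---------------------------------------------------------------------------


def _pack(pose: Pose) -> np.ndarray:
    return np.concatenate([pose.position, pose.orientation, pose.torsions])


def _unpack(topology: LigandTopology, v: np.ndarray) -> Pose:
    q = v[3:7]
    q = q / np.linalg.norm(q)
    return Pose(topology, position=v[:3].copy(), orientation=q, torsions=v[7:].copy())


def _quat_from_rotvec(rv: np.ndarray) -> np.ndarray:
    """Unit quaternion [x,y,z,w] for a rotation vector (angle * axis)."""
    angle = float(np.linalg.norm(rv))
    if angle < 1e-12:
        return np.array([0.0, 0.0, 0.0, 1.0])
    axis = rv / angle
    s = math.sin(angle / 2)
    return np.array([axis[0] * s, axis[1] * s, axis[2] * s, math.cos(angle / 2)])


def _quat_mul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a*b in [x,y,z,w] layout (apply b first, then a)."""
    ax, ay, az, aw = a
    bx, by, bz, bw = b
    return np.array([
        aw * bx + ax * bw + ay * bz - az * by,
        aw * by - ax * bz + ay * bw + az * bx,
        aw * bz + ax * by - ay * bx + az * bw,
        aw * bw - ax * bx - ay * by - az * bz,
    ])


def _perturb_orientation(q: np.ndarray, rotvec: np.ndarray) -> np.ndarray:
    out = _quat_mul(_quat_from_rotvec(rotvec), q)
    return out / np.linalg.norm(out)


def _wrap_angle(a: float) -> float:
    return (a + math.pi) % (2 * math.pi) - math.pi


class _BatchEvaluator:
    """Batched total energy of K parameter vectors -> (K,) energies."""

    def __init__(self, topology: LigandTopology, grids: GridMaps, params: ScoringParams):
        self.topology = topology
        self.grids = grids
        self.params = params
        self.n_evals = 0

    def __call__(self, V: np.ndarray) -> np.ndarray:
        from .searchscore import batch_total_energy
        from .structio import apply_pose_batch

        V = np.atleast_2d(V)
        self.n_evals += len(V)
        q = V[:, 3:7]
        q = q / np.linalg.norm(q, axis=1, keepdims=True)
        coords = apply_pose_batch(self.topology, V[:, :3], q, V[:, 7:])
        return batch_total_energy(self.grids, self.topology, coords, self.params)


def _rotate_vec(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector v by unit quaternion q ([x,y,z,w])."""
    u, w = q[:3], q[3]
    return v + 2.0 * np.cross(u, np.cross(u, v) + w * v)


def _centroid_offset(topology: LigandTopology) -> np.ndarray:
    """Heavy-atom centroid of the reference conformation relative to the
    root-frame origin (used to re-center rotation moves)."""
    off = topology._intra_cache.get("centroid_offset")
    if off is None:
        heavy = topology.heavy_indices()
        off = topology.ref_coords[heavy].mean(axis=0) - topology.root_origin()
        topology._intra_cache["centroid_offset"] = off
    return off


def _rotate_about_centroid(
    w: np.ndarray, rotvec: np.ndarray, a_ref: np.ndarray
) -> None:
    """In-place orientation move re-centered on the ligand centroid: rotate
    the molecule about its (approximate) heavy-atom centroid instead of the
    root origin, which keeps contacts intact and conditions the descent."""
    centroid = w[:3] + _rotate_vec(w[3:7], a_ref)
    w[3:7] = _perturb_orientation(w[3:7], rotvec)
    dq = _quat_from_rotvec(rotvec)
    w[:3] = centroid + _rotate_vec(dq, w[:3] - centroid)


def _neighbor_moves(
    best: np.ndarray,
    n_torsions: int,
    ts: float,
    rs: float,
    tos: float,
    a_ref: np.ndarray,
) -> np.ndarray:
    """All +/- pattern moves around ``best`` as a (2*(6+n), D) batch."""
    moves = []
    for k in range(3):
        for sign in (1.0, -1.0):
            w = best.copy()
            w[k] += sign * ts
            moves.append(w)
    for axis in range(3):
        for sign in (1.0, -1.0):
            w = best.copy()
            rotvec = np.zeros(3)
            rotvec[axis] = sign * rs
            _rotate_about_centroid(w, rotvec, a_ref)
            moves.append(w)
    for t in range(n_torsions):
        for sign in (1.0, -1.0):
            w = best.copy()
            w[7 + t] = _wrap_angle(w[7 + t] + sign * tos)
            moves.append(w)
    return np.stack(moves)


def pattern_refine(
    v: np.ndarray,
    energy,
    n_torsions: int,
    init_steps: tuple[float, float, float] = (0.6, 0.3, 0.3),
    min_translation_step: float = 0.05,
    max_iters: int = 120,
) -> tuple[np.ndarray, float]:
    """Derivative-free pattern search over (position, orientation, torsions).

    Each iteration evaluates every +/- move along the translation axes,
    rotation axes and torsions (one batched call) and takes the best
    improving neighbor; steps halve when no neighbor improves, and the
    search stops once the translation step drops below the floor.
    ``energy`` must accept a (K, D) batch and return (K,) energies.
    """
    a_ref = (
        _centroid_offset(energy.topology)
        if hasattr(energy, "topology") else np.zeros(3)
    )
    ts, rs, tos = init_steps
    best = v.copy()
    e_best = float(energy(best[None, :])[0])
    for _ in range(max_iters):
        moves = _neighbor_moves(best, n_torsions, ts, rs, tos, a_ref)
        energies = energy(moves)
        k = int(np.argmin(energies))
        if energies[k] < e_best:
            best, e_best = moves[k], float(energies[k])
        else:
            ts, rs, tos = ts / 2, rs / 2, tos / 2
            if ts < min_translation_step:
                break
    return best, e_best


def pattern_refine_batch(
    V: np.ndarray,
    energy,
    n_torsions: int,
    init_steps: tuple[float, float, float] = (0.6, 0.3, 0.3),
    min_translation_step: float = 0.05,
    max_iters: int = 120,
) -> tuple[np.ndarray, np.ndarray]:
    """Lockstep pattern search over a batch of T parameter vectors.

    Every iteration evaluates the pattern moves of all still-active vectors
    in a single batched energy call; per-vector step sizes halve
    independently when no neighbor improves.  With T=1 this is exactly
    :func:`pattern_refine`.
    """
    V = np.atleast_2d(V).copy()
    T = len(V)
    E = np.asarray(energy(V), dtype=float)
    ts = np.full(T, init_steps[0])
    rs = np.full(T, init_steps[1])
    tos = np.full(T, init_steps[2])
    active = np.ones(T, dtype=bool)
    n_moves = 2 * (6 + n_torsions)
    a_ref = (
        _centroid_offset(energy.topology)
        if hasattr(energy, "topology") else np.zeros(3)
    )
    for _ in range(max_iters):
        idx = np.nonzero(active)[0]
        if len(idx) == 0:
            break
        moves = np.stack(
            [_neighbor_moves(V[t], n_torsions, ts[t], rs[t], tos[t], a_ref)
             for t in idx]
        )  # (A, n_moves, D)
        Em = np.asarray(
            energy(moves.reshape(-1, V.shape[1]))
        ).reshape(len(idx), n_moves)
        k = np.argmin(Em, axis=1)
        e_new = Em[np.arange(len(idx)), k]
        improved = e_new < E[idx]
        imp = idx[improved]
        V[imp] = moves[improved, k[improved]]
        E[imp] = e_new[improved]
        stale = idx[~improved]
        ts[stale] /= 2
        rs[stale] /= 2
        tos[stale] /= 2
        active[stale] = ts[stale] >= min_translation_step
    return V, E


def _propose_hops(
    V: np.ndarray,
    rngs: list[np.random.Generator],
    config: DockingConfig,
    n_torsions: int,
    box: Box,
) -> np.ndarray:
    """Per-task basin-hop proposals (consumes each task's own RNG stream)."""
    cand = V.copy()
    for t, rng in enumerate(rngs):
        if rng.random() < config.reseed_probability:
            # escape hop: redraw position (center-biased), orientation, torsions
            cand[t, :3] = _draw_position(box, rng)
            q = rng.normal(size=4)
            cand[t, 3:7] = q / np.linalg.norm(q)
            if n_torsions:
                cand[t, 7:] = math.pi - rng.random(n_torsions) * (2 * math.pi)
        else:
            cand[t, :3] += rng.normal(0.0, config.translation_step, 3)
            cand[t, 3:7] = _perturb_orientation(
                cand[t, 3:7], rng.normal(0.0, config.rotation_step, 3)
            )
            if n_torsions:
                k = 7 + rng.integers(n_torsions)
                cand[t, k] = _wrap_angle(
                    cand[t, k] + rng.normal(0.0, config.torsion_step)
                )
    return cand


def _run_tasks(
    topology: LigandTopology,
    grids: GridMaps,
    config: DockingConfig,
    rngs: list[np.random.Generator],
    params: ScoringParams = DEFAULT_PARAMS,
) -> tuple[np.ndarray, np.ndarray]:
    """Basin-hopping Monte-Carlo over independent tasks, advanced in
    lockstep so each refinement iteration is one batched energy call.

    Each task owns its RNG stream, so results are independent of how tasks
    are grouped or ordered.  Returns (best vectors (T,D), best energies).
    """
    n_tors = topology.n_torsions
    energy = _BatchEvaluator(topology, grids, params)
    T = len(rngs)
    starts = []
    for rng in rngs:
        v = _pack(random_pose(topology, grids.box, rng))
        v[:3] = _draw_position(grids.box, rng)
        starts.append(v)
    V = np.stack(starts)
    V, E = pattern_refine_batch(
        V, energy, n_tors, init_steps=(0.8, 0.4, 0.4)
    )
    best, e_best = V.copy(), E.copy()
    kT = config.temperature
    for _ in range(config.budget(n_tors)):
        cand = _propose_hops(V, rngs, config, n_tors, grids.box)
        cand, Ec = pattern_refine_batch(cand, energy, n_tors)
        for t, rng in enumerate(rngs):
            de = Ec[t] - E[t]
            if de < 0 or rng.random() < math.exp(-min(de / kT, 50.0)):
                V[t], E[t] = cand[t], Ec[t]
                if Ec[t] < e_best[t]:
                    best[t], e_best[t] = cand[t], Ec[t]
    return best, e_best


def _hop_polish(
    V: np.ndarray,
    E: np.ndarray,
    energy,
    n_torsions: int,
    rng: np.random.Generator,
    rounds: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Escape shallow sub-basins around final poses: repeated rounds of a
    small correlated perturbation followed by a full refinement, keeping the
    better of old and new per pose.  Crosses the ridges that axis-aligned
    pattern moves cannot."""
    V, E = V.copy(), E.copy()
    for _ in range(rounds):
        cand = V.copy()
        for t in range(len(V)):
            cand[t, :3] += rng.normal(0.0, 0.35, 3)
            cand[t, 3:7] = _perturb_orientation(
                cand[t, 3:7], rng.normal(0.0, 0.2, 3)
            )
            for k in range(n_torsions):
                cand[t, 7 + k] = _wrap_angle(
                    cand[t, 7 + k] + rng.normal(0.0, 0.3)
                )
        cand, Ec = pattern_refine_batch(cand, energy, n_torsions)
        better = Ec < E
        V[better] = cand[better]
        E[better] = Ec[better]
    return V, E


def _finish_pose(
    topology: LigandTopology,
    v: np.ndarray,
    e_total: float,
    params: ScoringParams,
) -> Pose:
    pose = _unpack(topology, v)
    intra = intra_energy(topology, pose.coords, params)
    pose.score = normalized_score(e_total - intra, topology.n_torsions, params)
    return pose


def mc_task(
    topology: LigandTopology,
    grids: GridMaps,
    config: DockingConfig,
    rng: np.random.Generator,
    params: ScoringParams = DEFAULT_PARAMS,
) -> Pose:
    """One Monte-Carlo optimization task: basin hopping with Metropolis
    acceptance.  Starting from a random pose, each hop perturbs the current
    minimum, refines locally by pattern search, and accepts the refined
    candidate by the Metropolis rule; the best minimum ever visited is
    returned (non-increasing best-so-far by construction)."""
    best, e_best = _run_tasks(topology, grids, config, [rng], params)
    return _finish_pose(topology, best[0], float(e_best[0]), params)


def _distinct_filter(
    poses: list[Pose], threshold: float, max_poses: int
) -> list[Pose]:
    from .evaluation import rmsd

    kept: list[Pose] = []
    for pose in poses:
        if all(rmsd(pose.heavy_coords, k.heavy_coords) > threshold for k in kept):
            kept.append(pose)
        if len(kept) >= max_poses:
            break
    return kept


def dock(
    topology: LigandTopology,
    receptor: Receptor | None = None,
    box: Box | None = None,
    grids: GridMaps | None = None,
    config: DockingConfig = DockingConfig(),
    params: ScoringParams = DEFAULT_PARAMS,
    structure_id: str | None = None,
) -> DockResult:
    """Dock one compound: run independent MC tasks, pool their minima, keep
    up to ``max_poses`` mutually distinct poses sorted by ascending score.

    Either precomputed ``grids`` or a (receptor, box) pair must be given; in
    the latter case grids are built over a padded box at
    ``config.grid_spacing`` so that lattice clamping never bites inside the
    sampling box.
    """
    if grids is None:
        if receptor is None or box is None:
            raise ValueError("provide grids or both receptor and box")
        types = {a.ad_type for i, a in enumerate(topology.atoms) if a.is_heavy}
        grids = build_grids(
            receptor,
            box.padded(config.grid_padding),
            spacing=config.grid_spacing,
            ligand_types=types,
            params=params,
        )
    sid = structure_id or (receptor.structure_id if receptor else "grids")
    rngs = [task_rng(config.seed, i) for i in range(config.n_tasks)]
    best, e_best = _run_tasks(topology, grids, config, rngs, params)
    candidates = [
        _finish_pose(topology, best[i], float(e_best[i]), params)
        for i in range(config.n_tasks)
        if math.isfinite(e_best[i])
    ]
    candidates.sort(key=lambda p: p.score)
    poses = _distinct_filter(candidates, config.rmsd_threshold, config.max_poses)
    if config.polish_hops and poses:
        energy = _BatchEvaluator(topology, grids, params)
        V = np.stack([_pack(p) for p in poses])
        E = np.asarray(energy(V), dtype=float)
        rng = np.random.default_rng(
            np.random.SeedSequence((config.seed, 1_000_003))
        )
        V, E = _hop_polish(
            V, E, energy, topology.n_torsions, rng, config.polish_hops
        )
        poses = [
            _finish_pose(topology, V[i], float(E[i]), params)
            for i in range(len(V))
        ]
        poses.sort(key=lambda p: p.score)
        poses = _distinct_filter(poses, config.rmsd_threshold, config.max_poses)
    best = poses[0].score if poses else math.nan
    return DockResult(
        compound_id=topology.compound_id,
        structure_id=sid,
        poses=poses,
        best_score=best,
        diagnostics={
            "n_tasks": config.n_tasks,
            "n_candidates": len(candidates),
            "seed": config.seed,
        },
    )
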