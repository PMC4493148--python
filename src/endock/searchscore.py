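"""Search-space definition and the empirical scoring function.

The score is the five-term empirical free-energy function of the Vina family
(two attractive gaussians, a quadratic steric repulsion, a piecewise-linear
hydrophobic term and a piecewise-linear hydrogen-bond term), all functions of
the *surface* distance d = r - (R_a + R_b) between two atoms, truncated at a
cutoff, and normalized by 1/(1 + w_rot * N_rot).  It can be evaluated directly
(pair sums over receptor atoms) or through precomputed per-atom-type grid maps
with trilinear interpolation; the two routes agree to interpolation accuracy.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .structio import (
    ACCEPTOR_TYPES,
    DONOR_TYPES,
    HYDROPHOBIC_TYPES,
    LigandTopology,
    Pose,
    Receptor,
)

# ---------------------------------------------------------------------------
# Constants: vdW radii (heavy atoms only — hydrogens are not scored centers)
# and published default term weights.
# ---------------------------------------------------------------------------

XS_RADII: dict[str, float] = {
    "C": 1.9, "A": 1.9, "N": 1.8, "NA": 1.8, "O": 1.7, "OA": 1.7,
    "S": 2.0, "SA": 2.0, "P": 2.1, "F": 1.5, "Cl": 1.8, "Br": 2.0, "I": 2.2,
}
_METAL_RADIUS = 1.2  # coordinated metal ions


def vdw_radius(ad_type: str) -> float:
    if ad_type in XS_RADII:
        return XS_RADII[ad_type]
    from .structio import METAL_ELEMENTS

    if ad_type in METAL_ELEMENTS:
        return _METAL_RADIUS
    raise KeyError(f"no vdW radius for atom type {ad_type!r}")


@dataclass
class ScoringParams:
    """Term weights and geometry of the empirical scoring function."""

    w_gauss1: float = -0.035579
    w_gauss2: float = -0.005156
    w_repulsion: float = 0.840245
    w_hydrophobic: float = -0.035069
    w_hbond: float = -0.587439
    w_rot: float = 0.05846          # torsion penalty in the normalization
    cutoff: float = 8.0             # surface-distance cutoff, Angstrom
    boundary_k: float = 5.0         # kcal/mol/A^2 quadratic out-of-box penalty
    box_extension: float = 10.0     # added to the cube edge
    box_extension_mode: str = "edge"  # "edge" (+10 to edge) or "side" (+10 per side)

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


DEFAULT_PARAMS = ScoringParams()

TERM_NAMES = ("gauss1", "gauss2", "repulsion", "hydrophobic", "hbond")


# ---------------------------------------------------------------------------
# Search box
# ---------------------------------------------------------------------------


@dataclass
class Box:
    """Axis-aligned search space; cubic when built from a bound ligand."""

    center: np.ndarray
    edge: np.ndarray  # per-dimension lengths

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.edge = np.asarray(self.edge, dtype=float).reshape(3)
        if np.any(self.edge <= 0):
            raise ValueError("box edges must be positive")

    @property
    def lower(self) -> np.ndarray:
        return self.center - self.edge / 2

    @property
    def upper(self) -> np.ndarray:
        return self.center + self.edge / 2

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return np.all((p >= self.lower) & (p <= self.upper), axis=1)

    def outside_distance(self, points: np.ndarray) -> np.ndarray:
        """Per-point Euclidean distance to the box (0 inside)."""
        p = np.atleast_2d(points)
        d = np.maximum(self.lower - p, 0) + np.maximum(p - self.upper, 0)
        return np.linalg.norm(d, axis=1)

    def padded(self, margin: float) -> "Box":
        return Box(self.center.copy(), self.edge + 2 * margin)

    # Vina-config dialect serialization -------------------------------------
    def to_dict(self) -> dict:
        return {
            "center_x": float(self.center[0]),
            "center_y": float(self.center[1]),
            "center_z": float(self.center[2]),
            "size_x": float(self.edge[0]),
            "size_y": float(self.edge[1]),
            "size_z": float(self.edge[2]),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Box":
        return cls(
            center=[d["center_x"], d["center_y"], d["center_z"]],
            edge=[d["size_x"], d["size_y"], d["size_z"]],
        )


def box_from_ligand(
    ligand_coords: np.ndarray | Sequence,
    extension: float = 10.0,
    mode: str = "edge",
) -> Box:
    """Cubic search box from a bound ligand.

    The smallest cube covering the ligand (edge = maximum per-axis extent,
    centered on the bounding-box midpoint) is extended by ``extension``
    Angstrom: added to the edge length in ``"edge"`` mode (the default,
    i.e. +extension/2 per side) or to each side in ``"side"`` mode.
    """
    coords = np.atleast_2d(np.asarray(ligand_coords, dtype=float))
    if coords.size == 0:
        raise ValueError("cannot build a box from an empty coordinate list")
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    extent = float((hi - lo).max())
    edge = extent + (extension if mode == "edge" else 2.0 * extension)
    if edge <= 0:
        raise ValueError("resulting box edge is not positive")
    return Box(center=(lo + hi) / 2, edge=np.full(3, edge))


# ---------------------------------------------------------------------------
# Pair terms
# ---------------------------------------------------------------------------


def term_values(d: np.ndarray) -> dict[str, np.ndarray]:
    """Unweighted term shapes as functions of surface distance d (Angstrom)."""
    d = np.asarray(d, dtype=float)
    gauss1 = np.exp(-((d / 0.5) ** 2))
    gauss2 = np.exp(-(((d - 3.0) / 2.0) ** 2))
    repulsion = np.where(d < 0, d * d, 0.0)
    hydrophobic = np.clip(1.5 - d, 0.0, 1.0)
    hbond = np.clip(-d / 0.7, 0.0, 1.0)
    return {
        "gauss1": gauss1,
        "gauss2": gauss2,
        "repulsion": repulsion,
        "hydrophobic": hydrophobic,
        "hbond": hbond,
    }


def _pair_flags(type_a: str, type_b: str) -> tuple[bool, bool]:
    """(hydrophobic pair, hbond-capable pair) from the two atom types."""
    hydro = type_a in HYDROPHOBIC_TYPES and type_b in HYDROPHOBIC_TYPES
    hb = (type_a in DONOR_TYPES and type_b in ACCEPTOR_TYPES) or (
        type_b in DONOR_TYPES and type_a in ACCEPTOR_TYPES
    )
    return hydro, hb


def pair_energy(
    type_a: str,
    type_b: str,
    center_distance: float | np.ndarray,
    params: ScoringParams = DEFAULT_PARAMS,
) -> float | np.ndarray:
    """Weighted interaction energy of one atom pair at the given
    center-to-center distance; identically zero beyond the surface-distance
    cutoff."""
    r = np.asarray(center_distance, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    d = r - (vdw_radius(type_a) + vdw_radius(type_b))
    t = term_values(d)
    hydro, hb = _pair_flags(type_a, type_b)
    e = (
        params.w_gauss1 * t["gauss1"]
        + params.w_gauss2 * t["gauss2"]
        + params.w_repulsion * t["repulsion"]
    )
    if hydro:
        e = e + params.w_hydrophobic * t["hydrophobic"]
    if hb:
        e = e + params.w_hbond * t["hbond"]
    e = np.where(d > params.cutoff, 0.0, e)
    return float(e) if e.ndim == 0 else e


# ---------------------------------------------------------------------------
# Direct pose scoring
# ---------------------------------------------------------------------------


@dataclass
class ScoreBreakdown:
    inter: float
    intra: float
    terms: dict[str, float]
    normalized: float
    total: float  # inter + intra, the quantity the search minimizes


def _receptor_arrays(receptor: Receptor):
    """Cached heavy-atom coordinate/typing arrays for fast pair sums."""
    cache = getattr(receptor, "_score_arrays", None)
    if cache is not None:
        return cache
    heavy = receptor.heavy_atoms()
    coords = np.array([a.coords for a in heavy]).reshape(-1, 3)
    radii = np.array([vdw_radius(a.ad_type) for a in heavy])
    hydro = np.array([a.ad_type in HYDROPHOBIC_TYPES for a in heavy])
    donor = np.array([a.ad_type in DONOR_TYPES for a in heavy])
    acceptor = np.array([a.ad_type in ACCEPTOR_TYPES for a in heavy])
    cache = (coords, radii, hydro, donor, acceptor)
    receptor._score_arrays = cache  # type: ignore[attr-defined]
    return cache


def _ligand_arrays(topology: LigandTopology):
    cache = topology._intra_cache.get("lig_arrays")
    if cache is not None:
        return cache
    idx = topology.heavy_indices()
    types = [topology.atoms[i].ad_type for i in idx]
    radii = np.array([vdw_radius(t) for t in types])
    hydro = np.array([t in HYDROPHOBIC_TYPES for t in types])
    donor = np.array([t in DONOR_TYPES for t in types])
    acceptor = np.array([t in ACCEPTOR_TYPES for t in types])
    cache = (idx, types, radii, hydro, donor, acceptor)
    topology._intra_cache["lig_arrays"] = cache
    return cache


def _inter_terms(
    lig_coords: np.ndarray,
    lig_radii: np.ndarray,
    lig_hydro: np.ndarray,
    lig_donor: np.ndarray,
    lig_acceptor: np.ndarray,
    rec: tuple,
    params: ScoringParams,
) -> dict[str, float]:
    r_coords, r_radii, r_hydro, r_donor, r_acceptor = rec
    if len(r_coords) == 0 or len(lig_coords) == 0:
        return {k: 0.0 for k in TERM_NAMES}
    from scipy.spatial.distance import cdist

    r = cdist(lig_coords, r_coords)
    d = r - (lig_radii[:, None] + r_radii[None, :])
    within = d <= params.cutoff
    t = term_values(d)
    hydro_pair = lig_hydro[:, None] & r_hydro[None, :]
    hb_pair = (lig_donor[:, None] & r_acceptor[None, :]) | (
        lig_acceptor[:, None] & r_donor[None, :]
    )
    out = {
        "gauss1": float(np.sum(t["gauss1"] * within)),
        "gauss2": float(np.sum(t["gauss2"] * within)),
        "repulsion": float(np.sum(t["repulsion"] * within)),
        "hydrophobic": float(np.sum(t["hydrophobic"] * (within & hydro_pair))),
        "hbond": float(np.sum(t["hbond"] * (within & hb_pair))),
    }
    return out


def _weighted(terms: Mapping[str, float], params: ScoringParams) -> float:
    return (
        params.w_gauss1 * terms["gauss1"]
        + params.w_gauss2 * terms["gauss2"]
        + params.w_repulsion * terms["repulsion"]
        + params.w_hydrophobic * terms["hydrophobic"]
        + params.w_hbond * terms["hbond"]
    )


def intra_pairs(topology: LigandTopology) -> np.ndarray:
    """Heavy-atom pairs separated by >= 3 bonds (1-4 and beyond); these are
    the pairs whose geometry torsions can change."""
    key = "intra_pairs"
    if key in topology._intra_cache:
        return topology._intra_cache[key]
    gd = topology.graph_distances()
    idx = topology.heavy_indices()
    pairs = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            if gd[idx[a], idx[b]] >= 3:
                pairs.append((idx[a], idx[b]))
    out = np.array(pairs, dtype=int).reshape(-1, 2)
    topology._intra_cache[key] = out
    return out


def _fused_energy(
    d: np.ndarray,
    hydro_mask: np.ndarray,
    hb_mask: np.ndarray,
    params: ScoringParams,
) -> np.ndarray:
    """Weighted sum of all five terms over surface distances, with the pair
    masks selecting where hydrophobic/h-bond terms apply; zero past cutoff."""
    e = (
        params.w_gauss1 * np.exp(-((d / 0.5) ** 2))
        + params.w_gauss2 * np.exp(-(((d - 3.0) / 2.0) ** 2))
        + params.w_repulsion * np.where(d < 0, d * d, 0.0)
        + (params.w_hydrophobic * hydro_mask) * np.clip(1.5 - d, 0.0, 1.0)
        + (params.w_hbond * hb_mask) * np.clip(-d / 0.7, 0.0, 1.0)
    )
    e[d > params.cutoff] = 0.0
    return e


def _intra_arrays(topology: LigandTopology):
    """Precomputed (i, j, radii sum, hydrophobic mask, hbond mask) for the
    scored intra-molecular pairs."""
    key = "intra_arrays"
    if key in topology._intra_cache:
        return topology._intra_cache[key]
    pairs = intra_pairs(topology)
    types = [a.ad_type for a in topology.atoms]
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        rsum = np.array(
            [vdw_radius(types[a]) + vdw_radius(types[b]) for a, b in pairs]
        )
        flags = [_pair_flags(types[a], types[b]) for a, b in pairs]
        hydro = np.array([f[0] for f in flags], dtype=float)
        hb = np.array([f[1] for f in flags], dtype=float)
    else:
        i = j = np.zeros(0, dtype=int)
        rsum = hydro = hb = np.zeros(0)
    out = (i, j, rsum, hydro, hb)
    topology._intra_cache[key] = out
    return out


def intra_energy(
    topology: LigandTopology, coords: np.ndarray, params: ScoringParams
) -> float:
    i, j, rsum, hydro, hb = _intra_arrays(topology)
    if len(i) == 0:
        return 0.0
    r = np.linalg.norm(coords[i] - coords[j], axis=1)
    return float(np.sum(_fused_energy(r - rsum, hydro, hb, params)))


def normalized_score(inter: float, n_torsions: int, params: ScoringParams) -> float:
    """Reported free-energy estimate: inter-molecular energy scaled by the
    torsion penalty.  The intra-molecular energy of the pose itself is the
    reference, so it cancels out of the report (it still steers the search)."""
    return inter / (1.0 + params.w_rot * n_torsions)


def score_pose(
    receptor: Receptor,
    pose: Pose,
    params: ScoringParams = DEFAULT_PARAMS,
    box: Box | None = None,
) -> ScoreBreakdown:
    """Direct (grid-free) evaluation of the scoring function for one pose."""
    topo = pose.topology
    idx, types, radii, hydro, donor, acceptor = _ligand_arrays(topo)
    coords = pose.coords
    lig = coords[idx]
    terms = _inter_terms(
        lig, radii, hydro, donor, acceptor, _receptor_arrays(receptor), params
    )
    inter = _weighted(terms, params)
    if box is not None:
        dist_out = box.outside_distance(lig)
        inter += params.boundary_k * float(np.sum(dist_out**2))
    intra = intra_energy(topo, coords, params)
    norm = normalized_score(inter, topo.n_torsions, params)
    return ScoreBreakdown(
        inter=inter, intra=intra, terms=terms, normalized=norm, total=inter + intra
    )


# ---------------------------------------------------------------------------
# Grid maps
# ---------------------------------------------------------------------------

GRID_VALUE_CEILING = 1.0e4  # stored node values clamped here (deep clashes)


@dataclass
class GridMaps:
    """Per-atom-type lattices of receptor-field energies over a box.

    Node (i,j,k) sits at origin + (i,j,k)*spacing; lattice dimensions are
    floor(edge/spacing)+1 per axis, so the lattice spans the box from its
    lower corner.
    """

    box: Box
    spacing: float
    origin: np.ndarray
    dims: tuple[int, int, int]
    maps: dict[str, np.ndarray]

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.dims[axis]) * self.spacing

    @property
    def domain_upper(self) -> np.ndarray:
        return self.origin + (np.array(self.dims) - 1) * self.spacing

    def interpolate(self, ad_type: str, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Trilinear interpolation of one map at arbitrary points.

        Returns (values, outside_mask); outside points are clamped to the
        lattice boundary (the caller adds the boundary penalty).
        """
        if ad_type not in self.maps:
            raise KeyError(f"no grid map for atom type {ad_type!r}")
        grid = self.maps[ad_type]
        p = np.atleast_2d(points)
        t = (p - self.origin) / self.spacing
        dims = np.array(self.dims)
        outside = np.any((t < 0) | (t > dims - 1), axis=1)
        t = np.clip(t, 0, dims - 1)
        i0 = np.minimum(t.astype(int), dims - 2)
        f = t - i0
        ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
        fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
        c000 = grid[ix, iy, iz]
        c100 = grid[ix + 1, iy, iz]
        c010 = grid[ix, iy + 1, iz]
        c110 = grid[ix + 1, iy + 1, iz]
        c001 = grid[ix, iy, iz + 1]
        c101 = grid[ix + 1, iy, iz + 1]
        c011 = grid[ix, iy + 1, iz + 1]
        c111 = grid[ix + 1, iy + 1, iz + 1]
        c00 = c000 * (1 - fx) + c100 * fx
        c10 = c010 * (1 - fx) + c110 * fx
        c01 = c001 * (1 - fx) + c101 * fx
        c11 = c011 * (1 - fx) + c111 * fx
        c0 = c00 * (1 - fy) + c10 * fy
        c1 = c01 * (1 - fy) + c11 * fy
        return c0 * (1 - fz) + c1 * fz, outside

    # persistence: .npz payload with a JSON plain-text header entry ----------
    def save(self, path) -> None:
        meta = {
            "format": "endock-grids",
            "version": 1,
            "spacing": self.spacing,
            "dims": list(self.dims),
            "origin": self.origin.tolist(),
            "box": self.box.to_dict(),
            "types": sorted(self.maps),
        }
        arrays = {f"map_{t}": m for t, m in self.maps.items()}
        np.savez_compressed(path, header=json.dumps(meta, indent=1), **arrays)

    @classmethod
    def load(cls, path) -> "GridMaps":
        with np.load(path) as z:
            meta = json.loads(str(z["header"]))
            if meta.get("format") != "endock-grids":
                raise ValueError(f"{path}: not an endock grid container")
            maps = {t: z[f"map_{t}"] for t in meta["types"]}
        return cls(
            box=Box.from_dict(meta["box"]),
            spacing=meta["spacing"],
            origin=np.array(meta["origin"]),
            dims=tuple(meta["dims"]),
            maps=maps,
        )


def build_grids(
    receptor: Receptor,
    box: Box,
    spacing: float = 0.08,
    ligand_types: Iterable[str] = ("C",),
    params: ScoringParams = DEFAULT_PARAMS,
    memory_budget_bytes: int = 2_000_000_000,
) -> GridMaps:
    """Precompute receptor-field energies on a lattice for each probe type.

    For every requested AutoDock type and lattice node, the stored value is
    the exact direct sum of weighted pair terms between a probe of that type
    at the node and all receptor heavy atoms.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    ligand_types = sorted(set(ligand_types))
    dims = tuple(int(math.floor(e / spacing)) + 1 for e in box.edge)
    n_nodes = dims[0] * dims[1] * dims[2]
    need = n_nodes * len(ligand_types) * 8
    if need > memory_budget_bytes:
        raise MemoryError(
            f"grid of {dims} nodes x {len(ligand_types)} types needs "
            f"{need / 1e9:.1f} GB; use a coarser spacing"
        )
    origin = box.lower
    axes = [origin[k] + np.arange(dims[k]) * spacing for k in range(3)]
    rec_coords, rec_radii, rec_hydro, rec_donor, rec_acceptor = _receptor_arrays(
        receptor
    )
    maps = {t: np.zeros(dims) for t in ligand_types}
    rec_types = [a.ad_type for a in receptor.heavy_atoms()]
    for t in ligand_types:
        probe_radius = vdw_radius(t)
        grid = maps[t]
        for m in range(len(rec_coords)):
            rsum = probe_radius + rec_radii[m]
            reach = params.cutoff + rsum
            lo = rec_coords[m] - reach
            hi = rec_coords[m] + reach
            sl = []
            empty = False
            for k in range(3):
                a0 = int(np.searchsorted(axes[k], lo[k], side="left"))
                a1 = int(np.searchsorted(axes[k], hi[k], side="right"))
                if a0 >= a1:
                    empty = True
                    break
                sl.append((a0, a1))
            if empty:
                continue
            dx = axes[0][sl[0][0]:sl[0][1]] - rec_coords[m][0]
            dy = axes[1][sl[1][0]:sl[1][1]] - rec_coords[m][1]
            dz = axes[2][sl[2][0]:sl[2][1]] - rec_coords[m][2]
            r = np.sqrt(
                dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
            )
            d = r - rsum
            within = d <= params.cutoff
            tv = term_values(d)
            hydro, hb = _pair_flags(t, rec_types[m])
            e = (
                params.w_gauss1 * tv["gauss1"]
                + params.w_gauss2 * tv["gauss2"]
                + params.w_repulsion * tv["repulsion"]
            )
            if hydro:
                e += params.w_hydrophobic * tv["hydrophobic"]
            if hb:
                e += params.w_hbond * tv["hbond"]
            grid[sl[0][0]:sl[0][1], sl[1][0]:sl[1][1], sl[2][0]:sl[2][1]] += (
                e * within
            )
        np.clip(grid, -GRID_VALUE_CEILING, GRID_VALUE_CEILING, out=grid)
    return GridMaps(box=box, spacing=spacing, origin=origin, dims=dims, maps=maps)


def _type_groups(topology: LigandTopology) -> dict[str, np.ndarray]:
    """Heavy-atom positions grouped by AutoDock type (indices into the
    heavy-atom coordinate array), cached per topology."""
    by_type = topology._intra_cache.get("type_groups")
    if by_type is None:
        _, types, *_ = _ligand_arrays(topology)
        groups: dict[str, list[int]] = {}
        for k, t in enumerate(types):
            groups.setdefault(t, []).append(k)
        by_type = {t: np.array(ks) for t, ks in groups.items()}
        topology._intra_cache["type_groups"] = by_type
    return by_type


def grid_inter_energy(
    grids: GridMaps,
    topology: LigandTopology,
    coords: np.ndarray,
    params: ScoringParams = DEFAULT_PARAMS,
) -> float:
    """Inter-molecular energy of materialized coordinates by trilinear
    interpolation, including the quadratic out-of-box penalty."""
    idx = _ligand_arrays(topology)[0]
    lig = coords[idx]
    inter = 0.0
    for t, ks in _type_groups(topology).items():
        vals, _ = grids.interpolate(t, lig[ks])
        inter += float(np.sum(vals))
    dist_out = grids.box.outside_distance(lig)
    inter += params.boundary_k * float(np.sum(dist_out**2))
    return inter


def batch_total_energy(
    grids: GridMaps,
    topology: LigandTopology,
    coords_batch: np.ndarray,  # (K, n, 3)
    params: ScoringParams = DEFAULT_PARAMS,
) -> np.ndarray:
    """Total (inter + intra) energies of K materialized conformations in one
    vectorized pass; the batched counterpart of grid_score().total."""
    K, n, _ = coords_batch.shape
    idx = _ligand_arrays(topology)[0]
    lig = coords_batch[:, idx]  # (K, h, 3)
    h = len(idx)
    total = np.zeros(K)
    for t, ks in _type_groups(topology).items():
        pts = lig[:, ks].reshape(-1, 3)
        vals, _ = grids.interpolate(t, pts)
        total += vals.reshape(K, len(ks)).sum(axis=1)
    dist_out = grids.box.outside_distance(lig.reshape(-1, 3)).reshape(K, h)
    total += params.boundary_k * np.sum(dist_out**2, axis=1)
    i, j, rsum, hydro, hb = _intra_arrays(topology)
    if len(i):
        r = np.linalg.norm(coords_batch[:, i] - coords_batch[:, j], axis=2)
        d = r - rsum
        e = _fused_energy(d.ravel(), np.tile(hydro, K), np.tile(hb, K), params)
        total += e.reshape(K, len(i)).sum(axis=1)
    return total


def grid_score(
    grids: GridMaps,
    pose: Pose,
    params: ScoringParams = DEFAULT_PARAMS,
) -> ScoreBreakdown:
    """Grid-accelerated evaluation: inter-molecular energy by trilinear
    interpolation, intra-molecular energy computed directly."""
    topo = pose.topology
    coords = pose.coords
    inter = grid_inter_energy(grids, topo, coords, params)
    intra = intra_energy(topo, coords, params)
    norm = normalized_score(inter, topo.n_torsions, params)
    return ScoreBreakdown(
        inter=inter, intra=intra, terms={}, normalized=norm, total=inter + intra
    )
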