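"""Ensemble screening: dock every compound into every receptor, rank by the
mean best score across the ensemble, and summarize the score distribution.

Averaging the best score over the structures of the ensemble absorbs receptor
structural variability; compounds are ranked in ascending order of that mean
(more negative = stronger predicted binding).  The standard deviation is the
sample (n-1) standard deviation.  Per-(compound, structure) results are
cached on disk so interrupted screens resume and re-runs are byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .docking import DockingConfig, dock
from .searchscore import Box, DEFAULT_PARAMS, GridMaps, ScoringParams
from .structio import LigandTopology, Receptor

FAILURE_FLAG_FRACTION = 0.2  # flag compounds failing >20% of structures


def dedup_compounds(
    entries: Sequence[tuple[str, str]]
) -> tuple[list[tuple[str, str]], int]:
    """Keep the first occurrence of each compound id across catalogs.

    Returns (unique entries, duplicate count).
    """
    seen: set[str] = set()
    unique: list[tuple[str, str]] = []
    duplicates = 0
    for compound_id, catalog in entries:
        if compound_id in seen:
            duplicates += 1
            continue
        seen.add(compound_id)
        unique.append((compound_id, catalog))
    return unique, duplicates


@dataclass
class EnsembleResult:
    compound_id: str
    scores: dict[str, float]  # structure_id -> best score, successes only
    failures: list[str] = field(default_factory=list)

    @property
    def n_structures(self) -> int:
        return len(self.scores)

    @property
    def mean(self) -> float:
        if not self.scores:
            return math.nan
        return float(np.mean(list(self.scores.values())))

    @property
    def std(self) -> float:
        vals = list(self.scores.values())
        if len(vals) < 2:
            return 0.0 if vals else math.nan
        return float(np.std(vals, ddof=1))

    @property
    def usable(self) -> bool:
        return bool(self.scores)

    @property
    def flagged(self) -> bool:
        total = len(self.scores) + len(self.failures)
        return total > 0 and len(self.failures) / total > FAILURE_FLAG_FRACTION


def _pair_seed(base_seed: int, compound_id: str, structure_id: str) -> int:
    """Stable per-(compound, structure) seed, independent of run order."""
    h = zlib.crc32(f"{compound_id}|{structure_id}".encode())
    return int((base_seed * 2654435761 + h) % (2**31))


def _cache_key(
    compound_id: str, structure_id: str, config: DockingConfig,
    params: ScoringParams,
) -> str:
    payload = json.dumps(
        {
            "c": compound_id,
            "s": structure_id,
            "n_tasks": config.n_tasks,
            "seed": config.seed,
            "iterations": config.iterations,
            "spacing": config.grid_spacing,
            "weights": [
                params.w_gauss1, params.w_gauss2, params.w_repulsion,
                params.w_hydrophobic, params.w_hbond, params.w_rot,
            ],
        },
        sort_keys=True,
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:16]


def ensemble_dock(
    topology: LigandTopology,
    targets: Sequence[tuple[Receptor, Box | GridMaps]],
    config: DockingConfig = DockingConfig(),
    params: ScoringParams = DEFAULT_PARAMS,
    cache_dir: str | Path | None = None,
) -> EnsembleResult:
    """Dock one compound against every structure of the ensemble and collect
    the per-structure best scores; failed dockings are listed and excluded
    from the mean."""
    scores: dict[str, float] = {}
    failures: list[str] = []
    for receptor, space in targets:
        sid = receptor.structure_id
        cache_path = None
        if cache_dir is not None:
            key = _cache_key(topology.compound_id, sid, config, params)
            cache_path = Path(cache_dir) / f"{topology.compound_id}__{sid}__{key}.json"
            if cache_path.exists():
                payload = json.loads(cache_path.read_text())
                if math.isfinite(payload["best_score"]):
                    scores[sid] = payload["best_score"]
                else:
                    failures.append(sid)
                continue
        pair_cfg = DockingConfig(
            n_tasks=config.n_tasks,
            max_poses=config.max_poses,
            seed=_pair_seed(config.seed, topology.compound_id, sid),
            iterations=config.iterations,
            translation_step=config.translation_step,
            rotation_step=config.rotation_step,
            torsion_step=config.torsion_step,
            rmsd_threshold=config.rmsd_threshold,
            temperature=config.temperature,
            grid_spacing=config.grid_spacing,
            grid_padding=config.grid_padding,
        )
        if isinstance(space, GridMaps):
            result = dock(topology, grids=space, config=pair_cfg, params=params,
                          structure_id=sid)
        else:
            result = dock(topology, receptor=receptor, box=space,
                          config=pair_cfg, params=params)
        if result.ok:
            scores[sid] = result.best_score
        else:
            failures.append(sid)
        if cache_path is not None:
            cache_path.parent.mkdir(parents=True, exist_ok=True)
            cache_path.write_text(
                json.dumps(
                    {
                        "compound_id": topology.compound_id,
                        "structure_id": sid,
                        "best_score": result.best_score
                        if result.ok else math.nan,
                        "scores": [p.score for p in result.poses],
                        "n_tasks": pair_cfg.n_tasks,
                        "seed": pair_cfg.seed,
                    }
                )
            )
    return EnsembleResult(topology.compound_id, scores, failures)


@dataclass
class ScreenTable:
    """Ranked compound table (ascending mean score) plus library metadata."""

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.4f")


def rank(
    results: Sequence[EnsembleResult], metadata: dict | None = None
) -> ScreenTable:
    """Sort usable results ascending by mean score; ties broken by ascending
    std, then compound id."""
    usable = [r for r in results if r.usable]
    rows = [
        {
            "compound_id": r.compound_id,
            "mean_score": r.mean,
            "std_score": r.std,
            "n_structures": r.n_structures,
            "n_failures": len(r.failures),
            "flagged": r.flagged,
        }
        for r in usable
    ]
    frame = pd.DataFrame(
        rows,
        columns=[
            "compound_id", "mean_score", "std_score",
            "n_structures", "n_failures", "flagged",
        ],
    )
    if len(frame):
        frame = frame.sort_values(
            ["mean_score", "std_score", "compound_id"], kind="mergesort"
        ).reset_index(drop=True)
    return ScreenTable(frame, metadata or {})


def histogram(
    results: Sequence[EnsembleResult], bin_width: float = 0.5
) -> list[tuple[float, int]]:
    """Score histogram with upper-bound-inclusive bins.

    The bin with upper bound u holds scores s with u - bin_width < s <= u,
    so a mean of -10.46 falls in the (-10.5, -10.0] bin.  Bins are returned
    ascending by upper bound; counts sum to the number of usable results.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    means = [r.mean for r in results if r.usable]
    counts: dict[float, int] = {}
    for s in means:
        u = math.ceil(s / bin_width) * bin_width
        u = round(u, 10) + 0.0  # normalize -0.0
        counts[u] = counts.get(u, 0) + 1
    return sorted(counts.items())


def select_top(
    table: ScreenTable, score_ceiling: float = -10.0
) -> pd.DataFrame:
    """Rows with mean score at or below the ceiling ("-10 kcal/mol or
    lower")."""
    return table.frame[table.frame["mean_score"] <= score_ceiling].reset_index(
        drop=True
    )
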