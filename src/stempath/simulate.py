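"""Synthetic tree-structured scRNA-seq fixtures with planted programs.

The generator builds a random trajectory tree, scatters cells uniformly
along its edges with capture times that track pseudotime (so rooting
from real time is recoverable), and draws negative-binomial UMI counts
whose per-gene log-mean is piecewise-linear in pseudotime along one
target path: monotone up, monotone down, a transient mid-path peak, or
flat. The planted truth table lets the whole pipeline be scored end to
end without any external dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, write_counts
from .trajectory import (
    Placement,
    TrajectoryGraph,
    enumerate_paths,
    pseudotime_per_cell,
)

__all__ = [
    "ProgramSpec",
    "simulate_trajectory",
    "simulate_counts",
    "write_fixture",
    "write_trajectory_json",
]

PROGRAM_TYPES = ("up", "down", "transient", "flat")

# Study-scale defaults: ~5 UMI baseline per gene per cell (typical for a
# moderately expressed gene), a 1-natural-log (~2.7x) fold change across
# a path — a strong program without shifting the library composition the
# way an implausibly large fold change would — and mild NB overdispersion.
DEFAULT_BASELINE_MEAN = 5.0
DEFAULT_EFFECT_SIZE = 1.0
DEFAULT_DISPERSION = 0.3
N_CAPTURE_BINS = 5


@dataclass(frozen=True)
class ProgramSpec:
    """A planted gene program tied to one trajectory path."""

    program: str  # up / down / transient / flat
    path_id: int
    n_genes: int
    effect_size: float = DEFAULT_EFFECT_SIZE  # ln fold change over the path
    dispersion: float = DEFAULT_DISPERSION  # NB: var = mu (1 + dispersion * mu)

    def __post_init__(self) -> None:
        if self.program not in PROGRAM_TYPES:
            raise ValueError(f"program must be one of {PROGRAM_TYPES}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")


def simulate_trajectory(
    n_leaves: int, cells_per_edge: int = 100, seed: int = 0
) -> tuple[TrajectoryGraph, pd.DataFrame]:
    """Random binary-ish trajectory tree with uniformly placed cells.

    A chain of three edges when n_leaves is 1; otherwise leaves are
    repeatedly split until the leaf count is reached. Capture times are
    quantile bins of pseudotime (5 bins), mimicking discrete sampling
    days, so the true root minimizes nearby capture time.
    """
    if n_leaves < 1:
        raise ValueError("need at least one leaf")
    rng = np.random.default_rng(seed)
    edges: list[tuple] = []
    counter = 0

    def new_node() -> str:
        nonlocal counter
        name = f"M{counter}"
        counter += 1
        return name

    root = new_node()
    if n_leaves == 1:
        prev = root
        for _ in range(3):
            nxt = new_node()
            edges.append((prev, nxt, 1.0))
            prev = nxt
        leaves = [prev]
    else:
        first = new_node()
        edges.append((root, first, 1.0))
        leaves = [first]
        while len(leaves) < n_leaves:
            parent = leaves.pop(int(rng.integers(len(leaves))))
            for _ in range(2):
                child = new_node()
                edges.append((parent, child, 1.0))
                leaves.append(child)
    milestones = [f"M{i}" for i in range(counter)]

    placements: dict[str, Placement] = {}
    cell_counter = 0
    for ei in range(len(edges)):
        for _ in range(cells_per_edge):
            placements[f"cell_{cell_counter:05d}"] = Placement(
                edge_index=ei, percentage=float(rng.uniform())
            )
            cell_counter += 1
    traj = TrajectoryGraph(milestones=milestones, edges=edges, placements=placements)

    pt = pseudotime_per_cell(traj, root)
    cells = sorted(placements)
    pt_vals = np.array([pt[c] for c in cells])
    quantiles = np.quantile(pt_vals, np.linspace(0, 1, N_CAPTURE_BINS + 1)[1:-1])
    capture = np.searchsorted(quantiles, pt_vals, side="right").astype(float)
    meta = pd.DataFrame({"cell_id": cells, "capture_time": capture})
    return traj, meta


def _program_curve(program: str, s: np.ndarray, effect: float) -> np.ndarray:
    """Log-fold-change f(s) for normalized path position s in [0, 1]."""
    if program == "up":
        return effect * s
    if program == "down":
        return effect * (1.0 - s)  # starts elevated, decays to baseline
    if program == "transient":
        return effect * (1.0 - np.abs(2.0 * s - 1.0))  # peak at mid-path
    return np.zeros_like(s)


def simulate_counts(
    traj: TrajectoryGraph,
    programs: list[ProgramSpec],
    baseline_mean: float = DEFAULT_BASELINE_MEAN,
    seed: int = 0,
    root: str | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial UMI counts with planted path programs.

    Each program gene's mean is baseline * exp(f(s)) for cells on the
    target path (s = pseudotime / path length) and baseline elsewhere;
    counts are NB with var = mu (1 + dispersion * mu), Poisson in the
    dispersion -> 0 limit. Returns the matrix and the per-gene truth
    table (program type and target path).
    """
    rng = np.random.default_rng(seed)
    root = root if root is not None else traj.milestones[0]
    paths = enumerate_paths(traj, root)
    by_id = {p.path_id: p for p in paths}
    for spec in programs:
        if spec.path_id not in by_id:
            raise ValueError(f"program targets unknown path {spec.path_id}")
    pt = pseudotime_per_cell(traj, root)
    cells = sorted(traj.placements)
    cell_pos = {c: j for j, c in enumerate(cells)}
    n_cells = len(cells)

    # per path: member cell indices and normalized position s
    path_cells: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    lengths = {i: l for i, (_, _, l) in enumerate(traj.edges)}
    for p in paths:
        members = [
            c
            for c, plc in traj.placements.items()
            if plc.edge_index in set(p.edge_indices)
        ]
        idx = np.array([cell_pos[c] for c in members], dtype=int)
        total = sum(lengths[e] for e in p.edge_indices)
        s = np.array([pt[c] / total for c in members]) if total else np.zeros(0)
        path_cells[p.path_id] = (idx, np.clip(s, 0.0, 1.0))

    rows = []
    truth = []
    gi = 0
    for spec in programs:
        idx, s = path_cells[spec.path_id]
        for _ in range(spec.n_genes):
            gene = f"G{gi:05d}"
            gi += 1
            mu = np.full(n_cells, baseline_mean, dtype=float)
            mu[idx] = baseline_mean * np.exp(
                _program_curve(spec.program, s, spec.effect_size)
            )
            if spec.dispersion > 0:
                shape = 1.0 / spec.dispersion
                counts = rng.negative_binomial(shape, shape / (shape + mu))
            else:
                counts = rng.poisson(mu)
            rows.append(counts)
            truth.append((gene, spec.program, spec.path_id))
    matrix = CountMatrix(
        gene_ids=np.array([t[0] for t in truth], dtype=object),
        cell_ids=np.array(cells, dtype=object),
        counts=sp.csr_matrix(np.vstack(rows)),
    )
    truth_df = pd.DataFrame(truth, columns=["gene_id", "program", "path_id"])
    return matrix, truth_df


def write_trajectory_json(traj: TrajectoryGraph, path: str | Path) -> None:
    doc = {
        "milestone_ids": list(traj.milestones),
        "edges": [{"from": u, "to": v, "length": l} for u, v, l in traj.edges],
        "placements": [
            {"cell_id": c, "edge_index": p.edge_index, "percentage": p.percentage}
            for c, p in sorted(traj.placements.items())
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def write_fixture(
    out_dir: str | Path,
    traj: TrajectoryGraph,
    counts: CountMatrix,
    meta: pd.DataFrame,
    truth: pd.DataFrame,
) -> dict[str, Path]:
    """Emit MTX + TSVs + trajectory JSON + truth TSV readable by io."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "mtx": out / "counts.mtx",
        "genes": out / "genes.tsv",
        "cells": out / "cells.tsv",
        "cell_meta": out / "cell_meta.tsv",
        "trajectory": out / "trajectory.json",
        "truth": out / "truth.tsv",
    }
    write_counts(counts, files["mtx"], files["genes"], files["cells"])
    meta.to_csv(files["cell_meta"], sep="\t", index=False)
    write_trajectory_json(traj, files["trajectory"])
    truth.to_csv(files["truth"], sep="\t", index=False)
    return files
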