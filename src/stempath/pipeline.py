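"""End-to-end orchestration: config, logging, per-path outputs.

The pipeline wires the library modules together exactly as a scripted
analysis would: read and filter counts, log-normalize, root the
trajectory from capture times, enumerate and subdivide the paths, build
each path's gene x time-point series under the chosen metric, run the
profile-clustering engine, and write one TSV trio per path plus global
provenance files. Every output table starts with a '# columns:' comment
line declaring its schema.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as sio
from . import stem, summarize
from .trajectory import (
    PathUnusableError,
    classify_milestones,
    enumerate_paths,
    key_segments,
    pseudotime_per_cell,
    select_root,
    subdivide,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "prepare_paths"]

logger = logging.getLogger("stempath")


@dataclass
class RunConfig:
    """Validated inputs and parameters for one pipeline run."""

    mtx_path: str
    genes_path: str
    cells_path: str
    cell_meta_path: str
    trajectory_path: str
    out_dir: str
    metric: str = "mean"
    path_ids: list[int] | None = None  # None = all usable paths
    min_cells_per_gene: int = 10
    min_genes_per_cell: int = 200
    n_top_genes: int | None = None
    c: int = 2
    m: int = 50
    delta: float = 0.7
    alpha: float = 0.05
    n_perm: int = 500
    seed: int = 0

    def validate(self) -> None:
        if self.metric not in summarize.METRICS:
            raise ValueError(f"metric must be one of {summarize.METRICS}")
        for name in (
            "mtx_path",
            "genes_path",
            "cells_path",
            "cell_meta_path",
            "trajectory_path",
        ):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} = {p!r} does not exist")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.delta <= 1:
            raise ValueError("delta must be in (0, 1]")
        if self.c < 1 or self.m < 1 or self.n_perm < 1:
            raise ValueError("c, m and n_perm must be >= 1")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            doc = json.load(fh)
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)


@dataclass
class PipelineResult:
    root: str
    paths: list
    per_path: dict[int, dict]
    output_files: list[Path] = field(default_factory=list)


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None) -> None:
    with open(path, "w") as fh:
        cols = ([index_label] if index_label else []) + list(df.columns)
        fh.write("# columns: " + "\t".join(str(c) for c in cols) + "\n")
        df.to_csv(fh, sep="\t", index=index_label is not None,
                  index_label=index_label)


def prepare_paths(traj, cell_meta: pd.DataFrame):
    """Root, classify, enumerate, segment and subdivide; returns
    (root, pseudotime map, usable PathDefs, skipped path ids)."""
    root = select_root(traj, cell_meta)
    roles = classify_milestones(traj, root)
    pt = pseudotime_per_cell(traj, root)
    usable, skipped = [], []
    for path in enumerate_paths(traj, root):
        key_segments(traj, path, roles)
        try:
            subdivide(path, pt)
        except PathUnusableError as exc:
            warnings.warn(str(exc))
            skipped.append(path.path_id)
            continue
        usable.append(path)
    return root, pt, usable, skipped


def run_pipeline(config: RunConfig):
    """Execute the full analysis described by ``config``.

    Returns a PipelineResult; writes, under config.out_dir, per path:
    series / cluster / profile-stats TSVs, and globally: the path
    listing, a copy of the config and the run log.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    outputs: list[Path] = []
    try:
        (out / "config.json").write_text(
            json.dumps(dataclasses.asdict(config), indent=1)
        )
        outputs.append(out / "config.json")

        counts = sio.read_counts(
            config.mtx_path, config.genes_path, config.cells_path
        )
        logger.info("loaded counts: %d genes x %d cells", *counts.shape)
        meta = sio.read_cell_meta(config.cell_meta_path)
        traj = sio.read_trajectory(config.trajectory_path)

        counts = sio.filter_matrix(
            counts, config.min_cells_per_gene, config.min_genes_per_cell
        )
        # drop placements of filtered-out cells so paths see only kept cells
        kept = set(counts.cell_ids)
        traj.placements = {
            c: p for c, p in traj.placements.items() if c in kept
        }
        logger.info("after filtering: %d genes x %d cells", *counts.shape)
        normalized = sio.log_normalize(counts)
        if config.n_top_genes is not None:
            top = sio.select_variable_genes(normalized, config.n_top_genes)
            keep_idx = [
                i for i, g in enumerate(counts.gene_ids) if g in set(top)
            ]
            counts = sio.CountMatrix(
                gene_ids=counts.gene_ids[keep_idx],
                cell_ids=counts.cell_ids,
                counts=counts.counts[keep_idx],
            )
            normalized = sio.NormalizedMatrix(
                gene_ids=normalized.gene_ids[keep_idx],
                cell_ids=normalized.cell_ids,
                values=normalized.values[keep_idx],
                size_factors=normalized.size_factors,
            )

        root, pt, paths, skipped = prepare_paths(traj, meta)
        logger.info(
            "root %s; %d usable paths (%d skipped)", root, len(paths), len(skipped)
        )
        listing = pd.DataFrame(
            [
                {
                    "path_id": p.path_id,
                    "leaf": p.leaf,
                    "n_segments": len(p.segments),
                    "n_time_points": len(p.time_points),
                    "n_cells": sum(len(tp.cell_ids) for tp in p.time_points),
                }
                for p in paths
            ]
        )
        _write_tsv(listing, out / "paths.tsv", index_label=None)
        outputs.append(out / "paths.tsv")

        selected = (
            paths
            if config.path_ids is None
            else [p for p in paths if p.path_id in set(config.path_ids)]
        )
        per_path = {}
        for path in selected:
            series = summarize.build_series(
                path, counts, normalized, config.metric, pseudotime=pt
            )
            assignment, stats, clusters = stem.cluster_path(
                series,
                c=config.c,
                m=config.m,
                delta=config.delta,
                alpha=config.alpha,
                n_perm=config.n_perm,
                seed=config.seed,
                path_id=path.path_id,
            )
            prefix = out / f"path{path.path_id}"
            _write_tsv(series, Path(f"{prefix}_series.tsv"), "gene_id")
            cluster_of = {}
            for cl in clusters:
                for g in cl.gene_ids:
                    cluster_of[g] = cl.cluster_id
            gene_table = pd.DataFrame(
                {
                    "profile_id": assignment,
                    "cluster_id": [
                        cluster_of.get(g, -1) for g in assignment.index
                    ],
                }
            )
            _write_tsv(gene_table, Path(f"{prefix}_clusters.tsv"), "gene_id")
            stats_table = pd.DataFrame([vars(s) for s in stats])
            _write_tsv(stats_table, Path(f"{prefix}_profile_stats.tsv"), None)
            outputs += [
                Path(f"{prefix}_series.tsv"),
                Path(f"{prefix}_clusters.tsv"),
                Path(f"{prefix}_profile_stats.tsv"),
            ]
            per_path[path.path_id] = {
                "series": series,
                "assignment": assignment,
                "stats": stats,
                "clusters": clusters,
            }
            logger.info(
                "path %d: %d significant profiles, %d clusters",
                path.path_id,
                sum(s.significant for s in stats),
                len(clusters),
            )
        return PipelineResult(
            root=root, paths=paths, per_path=per_path, output_files=outputs
        )
    finally:
        logger.removeHandler(handler)
        handler.close()
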