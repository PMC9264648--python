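"""Readers, writers, preprocessing filters and log-normalization.

External formats handled here: Matrix Market coordinate integer matrices
with companion gene/cell TSV files, a JSON trajectory description
(dynverse-inspired: milestones, weighted edges, fractional cell
placements), and GMT gene-set files. Everything downstream works on the
in-memory containers defined in this module.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .trajectory import TrajectoryGraph, Placement

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "FormatError",
    "read_counts",
    "write_counts",
    "read_cell_meta",
    "read_trajectory",
    "filter_matrix",
    "log_normalize",
    "select_variable_genes",
    "read_gene_sets",
]


class FormatError(ValueError):
    """An input file violates its declared format."""


@dataclass
class CountMatrix:
    """Sparse genes x cells matrix of nonnegative integer UMI counts."""

    gene_ids: np.ndarray  # unique strings, one per row
    cell_ids: np.ndarray  # unique strings, one per column
    counts: sp.csr_matrix  # genes x cells, nonnegative integers

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.counts = sp.csr_matrix(self.counts)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("gene ids are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise FormatError("cell ids are not unique")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise FormatError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise FormatError("non-integer counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        """Dense DataFrame view (small matrices only)."""
        return pd.DataFrame(
            self.counts.toarray(), index=self.gene_ids, columns=self.cell_ids
        )


@dataclass
class NormalizedMatrix:
    """Log-normalized expression with the per-cell size factors used."""

    gene_ids: np.ndarray
    cell_ids: np.ndarray
    values: sp.csr_matrix  # ln(count / size_factor + 1)
    size_factors: np.ndarray  # one positive real per cell

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.toarray(), index=self.gene_ids, columns=self.cell_ids
        )


def _read_id_column(path: str | Path) -> np.ndarray:
    """First whitespace/tab-delimited column of a headerless TSV."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ids.append(line.split("\t")[0])
    return np.asarray(ids, dtype=object)


def read_counts(
    mtx_path: str | Path, genes_path: str | Path, cells_path: str | Path
) -> CountMatrix:
    """Read a Matrix Market counts file with companion gene/cell id TSVs.

    The MTX file is coordinate-format with 1-based indices per the
    standard; indices are 0-based internally.
    """
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"cannot parse Matrix Market file {mtx_path}: {exc}")
    mat = sp.csr_matrix(mat)
    gene_ids = _read_id_column(genes_path)
    cell_ids = _read_id_column(cells_path)
    if len(gene_ids) != mat.shape[0]:
        raise FormatError(
            f"gene file lists {len(gene_ids)} ids but matrix has "
            f"{mat.shape[0]} rows"
        )
    if len(cell_ids) != mat.shape[1]:
        raise FormatError(
            f"cell file lists {len(cell_ids)} ids but matrix has "
            f"{mat.shape[1]} columns"
        )
    return CountMatrix(gene_ids=gene_ids, cell_ids=cell_ids, counts=mat)


def write_counts(
    matrix: CountMatrix,
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> None:
    """Inverse of :func:`read_counts`; round-trips integer matrices exactly."""
    scipy.io.mmwrite(
        str(mtx_path), sp.coo_matrix(matrix.counts.astype(np.int64)), field="integer"
    )
    Path(genes_path).write_text("".join(f"{g}\n" for g in matrix.gene_ids))
    Path(cells_path).write_text("".join(f"{c}\n" for c in matrix.cell_ids))


def read_cell_meta(path: str | Path) -> pd.DataFrame:
    """Cell metadata TSV with header; requires cell_id and capture_time."""
    meta = pd.read_csv(path, sep="\t")
    for col in ("cell_id", "capture_time"):
        if col not in meta.columns:
            raise FormatError(f"cell metadata lacks required column {col!r}")
    if not np.all(np.isfinite(meta["capture_time"].to_numpy(dtype=float))):
        raise FormatError("non-finite capture_time")
    return meta


def read_trajectory(json_path: str | Path) -> TrajectoryGraph:
    """Read a trajectory-tree JSON produced by an external inference tool.

    Schema::

        {"milestone_ids": [...],
         "edges": [{"from": ..., "to": ..., "length": ...}, ...],
         "placements": [{"cell_id": ..., "edge_index": ..., "percentage": ...}, ...]}

    The graph must be a tree (connected, acyclic, no self-edges); every
    placement must name an existing edge and lie in [0, 1].
    """
    with open(json_path) as fh:
        doc = json.load(fh)
    milestones = list(doc["milestone_ids"])
    edges = [
        (e["from"], e["to"], float(e.get("length", 1.0))) for e in doc["edges"]
    ]
    placements = {}
    for p in doc.get("placements", []):
        idx = int(p["edge_index"])
        if not 0 <= idx < len(edges):
            raise FormatError(
                f"placement for cell {p['cell_id']!r} names unknown edge {idx}"
            )
        pct = float(p["percentage"])
        if not 0.0 <= pct <= 1.0:
            raise FormatError(
                f"placement percentage {pct} for cell {p['cell_id']!r} "
                "outside [0, 1]"
            )
        placements[p["cell_id"]] = Placement(edge_index=idx, percentage=pct)
    return TrajectoryGraph(milestones=milestones, edges=edges, placements=placements)


def filter_matrix(
    matrix: CountMatrix,
    min_cells_per_gene: int = 10,
    min_genes_per_cell: int = 200,
) -> CountMatrix:
    """Drop rarely expressed genes, then sparsely covered cells.

    Genes kept when nonzero in at least ``min_cells_per_gene`` cells;
    cells kept when they express at least ``min_genes_per_cell`` of the
    *retained* genes. Each pass runs exactly once, genes first.
    """
    if min_cells_per_gene < 0 or min_genes_per_cell < 0:
        raise ValueError("thresholds must be nonnegative")
    counts = matrix.counts
    gene_keep = np.asarray((counts > 0).sum(axis=1)).ravel() >= min_cells_per_gene
    if not gene_keep.any():
        raise ValueError(
            "every gene fell below the min-cells threshold; nothing retained"
        )
    counts = counts[gene_keep]
    cell_keep = np.asarray((counts > 0).sum(axis=0)).ravel() >= min_genes_per_cell
    if not cell_keep.any():
        raise ValueError(
            "every cell fell below the min-genes threshold; nothing retained"
        )
    return CountMatrix(
        gene_ids=matrix.gene_ids[gene_keep],
        cell_ids=matrix.cell_ids[cell_keep],
        counts=counts[:, cell_keep],
    )


def log_normalize(matrix: CountMatrix) -> NormalizedMatrix:
    """Size-factor log normalization.

    size_factor_j = (total of cell j) / median(cell totals);
    value_ij = ln(count_ij / size_factor_j + 1). Zeros are preserved
    exactly and the map is strictly monotone within a cell.
    """
    totals = np.asarray(matrix.counts.sum(axis=0), dtype=float).ravel()
    if np.any(totals == 0):
        bad = matrix.cell_ids[totals == 0][:5]
        raise ValueError(
            f"cells with zero total counts (e.g. {list(bad)}); "
            "apply filter_matrix first"
        )
    size_factors = totals / np.median(totals)
    scaled = matrix.counts.astype(float).tocsc()
    # divide each column's stored entries by its size factor, then log1p
    sf_per_entry = np.repeat(size_factors, np.diff(scaled.indptr))
    scaled.data = np.log1p(scaled.data / sf_per_entry)
    return NormalizedMatrix(
        gene_ids=matrix.gene_ids,
        cell_ids=matrix.cell_ids,
        values=scaled.tocsr(),
        size_factors=size_factors,
    )


def select_variable_genes(norm: NormalizedMatrix, k: int) -> list:
    """The k genes with largest variance of log-normalized expression.

    Ties broken by gene id order. Asking for more genes than exist
    returns all of them with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_genes, n_cells = norm.shape
    vals = norm.values
    mean = np.asarray(vals.mean(axis=1)).ravel()
    sq = vals.copy()
    sq.data = sq.data**2
    var = np.asarray(sq.mean(axis=1)).ravel() - mean**2
    var = np.maximum(var, 0.0)
    order = sorted(range(n_genes), key=lambda i: (-var[i], norm.gene_ids[i]))
    if k >= n_genes:
        if k > n_genes:
            warnings.warn(
                f"requested {k} variable genes but only {n_genes} available; "
                "returning all"
            )
        return [norm.gene_ids[i] for i in order]
    return [norm.gene_ids[i] for i in order[:k]]


def read_gene_sets(gmt_path: str | Path) -> dict[str, set]:
    """Parse a GMT file into {set name: member gene ids}.

    One set per non-empty line: name, description, then members,
    tab-separated. Duplicate members within a set are stored once.
    """
    sets: dict[str, set] = {}
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{gmt_path}:{lineno}: GMT line has {len(fields)} fields, "
                    "need at least name, description and one member"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{gmt_path}:{lineno}: duplicate set {name!r}")
            members = {g for g in fields[2:] if g}
            if not members:
                raise FormatError(f"{gmt_path}:{lineno}: set {name!r} is empty")
            sets[name] = members
    return sets
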