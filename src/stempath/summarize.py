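"""Per-time-point expression summaries and the linearity diagnostic.

Each gene's expression over a path is compressed to one value per
sampled time point using one of three metrics:

* ``mean`` — arithmetic mean of log-normalized expression;
* ``entropy`` — an entropy-reduction score on raw counts, the gap
  between the log of the mean count and the mean of the log counts
  (zero exactly when all cells agree; larger the more heterogeneous);
* ``rate`` — the slope of log-normalized expression on pseudotime
  after a |Z| > 1.96 outlier filter.

The resulting genes x time-points matrix is the short time series fed
to the profile-clustering engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, NormalizedMatrix
from .trajectory import PathDef, TrajectoryGraph

__all__ = [
    "ChangeRateFit",
    "mean_expression",
    "entropy_reduction",
    "change_rate",
    "build_series",
    "linearity_diagnostic",
    "METRICS",
]

METRICS = ("mean", "entropy", "rate")

Z_CUTOFF = 1.96  # two-sided normal 95% bound for the dropout/outlier filter


@dataclass
class ChangeRateFit:
    """OLS slope of expression on pseudotime within one time point."""

    slope: float
    intercept: float
    residual_sd: float
    n_retained: int
    degenerate: bool = False


def mean_expression(values: np.ndarray) -> float:
    """Arithmetic mean of (log-normalized) expression over the cells."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty time point")
    return float(values.mean())


def entropy_reduction(counts: np.ndarray, pseudocount: float = 1.0) -> float:
    """Entropy gap ds = ln(mean(X + 1)) - mean(ln(X + 1)) on raw counts.

    Nonnegative by Jensen's inequality on the concave logarithm, and
    exactly zero when all counts are equal (including n = 1). The
    pseudocount keeps the score defined at zero counts without breaking
    either property.
    """
    x = np.asarray(counts, dtype=float) + pseudocount
    if x.size == 0:
        raise ValueError("empty time point")
    return float(np.log(x.mean()) - np.log(x).mean())


def change_rate(
    values: np.ndarray, pseudotimes: np.ndarray, z_cutoff: float = Z_CUTOFF
) -> ChangeRateFit:
    """Slope of expression on pseudotime after Z-score outlier removal.

    Cells whose expression Z-score (within the time point) exceeds the
    cutoff in absolute value are dropped before an ordinary
    least-squares fit of e = beta * t + eps. Fits with fewer than two
    retained cells or no pseudotime spread return slope 0, flagged
    degenerate, so every gene still yields a complete series.
    """
    e = np.asarray(values, dtype=float)
    t = np.asarray(pseudotimes, dtype=float)
    if e.shape != t.shape:
        raise ValueError("expression and pseudotime lengths differ")
    sd = e.std()
    if sd > 0:
        z = (e - e.mean()) / sd
        keep = np.abs(z) <= z_cutoff
    else:
        keep = np.ones_like(e, dtype=bool)
    e, t = e[keep], t[keep]
    n = int(keep.sum())
    if n < 2 or t.std() == 0:
        return ChangeRateFit(0.0, float(e.mean()) if n else 0.0, 0.0, n, True)
    tc = t - t.mean()
    slope = float(np.dot(tc, e) / np.dot(tc, tc))
    intercept = float(e.mean() - slope * t.mean())
    resid = e - (intercept + slope * t)
    return ChangeRateFit(slope, intercept, float(resid.std()), n, False)


def _column(values: sp.spmatrix, col_idx: np.ndarray) -> np.ndarray:
    return np.asarray(values[:, col_idx].todense())


def _change_rate_rows(block: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Row-wise change_rate over a genes x cells block (vectorized)."""
    sd = block.std(axis=1, keepdims=True)
    mean = block.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (block - mean) / sd, 0.0)
    keep = np.abs(z) <= Z_CUTOFF
    n = keep.sum(axis=1)
    tsum = keep @ t
    esum = (block * keep).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sxx = keep @ t**2 - tsum**2 / n
        sxy = (block * keep) @ t - tsum * esum / n
        slope = np.where((n >= 2) & (sxx > 1e-300), sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    return np.where(np.isfinite(slope), slope, 0.0)


def build_series(
    path: PathDef,
    counts: CountMatrix,
    normalized: NormalizedMatrix,
    metric: str,
    pseudotime: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Genes x sampled-time-points summary matrix for one path.

    Columns follow pseudotime order. The entropy metric reads raw
    counts; mean and rate read log-normalized values; rate additionally
    needs the per-cell ``pseudotime`` map.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    if metric == "rate" and pseudotime is None:
        raise ValueError("metric 'rate' requires the pseudotime map")
    if not path.time_points:
        raise ValueError("path has no sampled time points; call subdivide first")
    cell_pos = {c: j for j, c in enumerate(counts.cell_ids)}
    out = np.empty((len(counts.gene_ids), len(path.time_points)))
    for k, tp in enumerate(path.time_points):
        if not tp.cell_ids:
            raise ValueError(f"empty sampled time point {tp.index}")
        idx = np.array([cell_pos[c] for c in tp.cell_ids])
        if metric == "mean":
            block = _column(normalized.values, idx)
            out[:, k] = block.mean(axis=1)
        elif metric == "entropy":
            block = _column(counts.counts, idx)
            xp = block + 1.0
            out[:, k] = np.log(xp.mean(axis=1)) - np.log(xp).mean(axis=1)
        else:  # rate
            block = _column(normalized.values, idx)
            t = np.array([pseudotime[c] for c in tp.cell_ids], dtype=float)
            out[:, k] = _change_rate_rows(block, t)
    return pd.DataFrame(
        out,
        index=counts.gene_ids,
        columns=[f"tp{tp.index}" for tp in path.time_points],
    )


def linearity_diagnostic(
    edge_cells: list[str],
    normalized: NormalizedMatrix,
    pseudotime: dict[str, float],
    min_expressed_fraction: float = 0.05,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Per-gene linear-fit diagnostic within one trajectory edge.

    For genes expressed in at least ``min_expressed_fraction`` of the
    edge's cells, fits expression ~ pseudotime by OLS and tests the
    slope against the intercept-only model with an F test
    (F = (n-2) R^2 / (1 - R^2)), then BH-corrects across tested genes.
    """
    if len(edge_cells) < min_cells:
        raise ValueError(
            f"edge has {len(edge_cells)} cells (< {min_cells}); skipped"
        )
    cell_pos = {c: j for j, c in enumerate(normalized.cell_ids)}
    idx = np.array([cell_pos[c] for c in edge_cells])
    block = np.asarray(normalized.values[:, idx].todense())
    expressed = (block > 0).mean(axis=1) >= min_expressed_fraction
    block = block[expressed]
    genes = normalized.gene_ids[expressed]
    t = np.array([pseudotime[c] for c in edge_cells], dtype=float)
    n = len(t)
    tc = t - t.mean()
    sst_t = np.dot(tc, tc)
    if sst_t == 0:
        raise ValueError("edge cells have identical pseudotime")
    ec = block - block.mean(axis=1, keepdims=True)
    slope = ec @ tc / sst_t
    ss_tot = (ec**2).sum(axis=1)
    ss_reg = slope**2 * sst_t
    ss_res = np.maximum(ss_tot - ss_reg, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = np.where(
            ss_tot > 0, ss_reg / np.maximum(ss_res, 0.0) * (n - 2), 0.0
        )
    f_stat = np.where(np.isfinite(f_stat), f_stat, np.inf)
    pvals = scipy.stats.f.sf(f_stat, 1, n - 2)
    # a perfect fit underflows; report the smallest representable p
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    if len(pvals):
        _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        p_adj = pvals
    return pd.DataFrame(
        {"gene_id": genes, "slope": slope, "p_value": pvals, "p_adjusted": p_adj}
    ).set_index("gene_id")
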