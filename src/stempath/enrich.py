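"""Hypergeometric machinery: cross-path cluster overlap, gene-set
enrichment from GMT collections, and marker-list enrichment.

All tests share one primitive, the upper-tail hypergeometric
probability P(X >= k) of drawing at least k special genes in a sample
of n from a universe of N containing K specials, accumulated in log
space so extreme tails stay accurate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .stem import ClusterResult

__all__ = [
    "OverlapRecord",
    "EnrichmentRecord",
    "hypergeom_upper",
    "compare_paths",
    "geneset_enrichment",
    "marker_enrichment",
]


@dataclass
class OverlapRecord:
    """Overlap between one cluster of path A and one of path B."""

    cluster_a: int
    cluster_b: int
    overlap: int
    size_a: int
    size_b: int
    background: int
    p_value: float
    p_adjusted: float


@dataclass
class EnrichmentRecord:
    """Hypergeometric enrichment of a query gene list in one gene set."""

    set_name: str
    overlap: int
    set_size: int
    query_size: int
    background: int
    fold_enrichment: float
    p_value: float
    p_adjusted: float


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    Summed over the exact log-pmf with logsumexp, so tails far below
    float underflow of individual cumulative routines remain stable.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent arguments K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        if k > min(K, n):
            raise ValueError(f"k={k} exceeds min(K={K}, n={n})")
        raise ValueError(f"k={k} negative")
    if k == 0:
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    logp = scipy.stats.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def compare_paths(
    result_a: list[ClusterResult],
    result_b: list[ClusterResult],
    universe_a: set,
    universe_b: set,
) -> pd.DataFrame:
    """All-pairs hypergeometric overlap between two paths' clusters.

    The background is the intersection of the two runs' gene universes;
    genes outside it are excluded from every count. P-values are BH
    corrected over all cluster pairs and records sorted by corrected p.
    """
    background = set(universe_a) & set(universe_b)
    if not background:
        raise ValueError("the two gene universes do not intersect")
    N = len(background)
    records = []
    for ca, cb in itertools.product(result_a, result_b):
        genes_a = set(ca.gene_ids) & background
        genes_b = set(cb.gene_ids) & background
        k = len(genes_a & genes_b)
        p = hypergeom_upper(k, len(genes_a), len(genes_b), N)
        records.append(
            OverlapRecord(
                cluster_a=ca.cluster_id,
                cluster_b=cb.cluster_id,
                overlap=k,
                size_a=len(genes_a),
                size_b=len(genes_b),
                background=N,
                p_value=p,
                p_adjusted=p,
            )
        )
    if records:
        _, p_adj, _, _ = multipletests(
            [r.p_value for r in records], method="fdr_bh"
        )
        for r, pa in zip(records, p_adj):
            r.p_adjusted = float(pa)
        records.sort(key=lambda r: (r.p_adjusted, r.p_value, r.cluster_a, r.cluster_b))
    return pd.DataFrame([vars(r) for r in records])


def geneset_enrichment(
    query_genes: set,
    gene_sets: dict[str, set],
    background: set,
    rank_by: str = "fold",
) -> pd.DataFrame:
    """Hypergeometric enrichment of a query list against each gene set.

    Sets are restricted to the background before counting; fold
    enrichment is (k/n) / (K/N). BH correction runs across all sets.
    Default ranking by fold enrichment (descending); ``rank_by='p'``
    sorts by corrected p instead.
    """
    query = set(query_genes) & set(background)
    if not query:
        raise ValueError("query is empty (or disjoint from the background)")
    if rank_by not in ("fold", "p"):
        raise ValueError("rank_by must be 'fold' or 'p'")
    N = len(background)
    n = len(query)
    records = []
    for name, members in gene_sets.items():
        in_bg = set(members) & set(background)
        K = len(in_bg)
        k = len(query & in_bg)
        fold = (k / n) / (K / N) if K else 0.0
        p = hypergeom_upper(k, K, n, N) if K else 1.0
        records.append(
            EnrichmentRecord(
                set_name=name,
                overlap=k,
                set_size=K,
                query_size=n,
                background=N,
                fold_enrichment=fold,
                p_value=p,
                p_adjusted=p,
            )
        )
    if records:
        _, p_adj, _, _ = multipletests(
            [r.p_value for r in records], method="fdr_bh"
        )
        for r, pa in zip(records, p_adj):
            r.p_adjusted = float(pa)
    if rank_by == "fold":
        records.sort(key=lambda r: (-r.fold_enrichment, r.p_adjusted, r.set_name))
    else:
        records.sort(key=lambda r: (r.p_adjusted, r.p_value, r.set_name))
    return pd.DataFrame([vars(r) for r in records])


def marker_enrichment(
    cluster_genes: set, marker_list: set, background_size: int
) -> EnrichmentRecord:
    """Enrichment of a marker list in one cluster.

    The background size is a plain count because marker validations are
    typically run against a genome-wide universe (e.g. all protein
    coding genes) that is larger than any loaded matrix.
    """
    markers = set(marker_list)
    if not markers:
        raise ValueError("marker list is empty")
    if background_size < len(markers):
        raise ValueError("background smaller than the marker list")
    cluster = set(cluster_genes)
    k = len(cluster & markers)
    K = len(markers)
    n = len(cluster)
    N = int(background_size)
    p = hypergeom_upper(k, K, n, N)
    fold = (k / n) / (K / N) if n else 0.0
    return EnrichmentRecord(
        set_name="markers",
        overlap=k,
        set_size=K,
        query_size=n,
        background=N,
        fold_enrichment=fold,
        p_value=p,
        p_adjusted=p,
    )
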