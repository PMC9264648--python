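"""Profile-based clustering of short expression time series.

The engine pre-generates all integer "model profiles" of unit changes
(starting at 0, each step bounded by ±c), greedily selects a distinct
subset by maximizing the minimum correlation distance, assigns each
gene's log-ratio series to its closest profile, attaches permutation
significance to each profile's gene count via a binomial upper tail on
the permutation-expected assignment proportions, and finally merges
correlated significant profiles into clusters.

Because assignment distance is 1 - Pearson correlation — invariant to
the additive shift that anchors a series at its first time point —
permuting the already-transformed series columns is exactly equivalent
to permuting the raw series and re-anchoring.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "ModelProfile",
    "ProfileSet",
    "ProfileStats",
    "ClusterResult",
    "log_ratio_transform",
    "generate_profiles",
    "select_profiles",
    "assign_genes",
    "permutation_significance",
    "group_profiles",
    "cluster_path",
]

EXACT_PERMUTATION_LIMIT = 5040  # enumerate all T! permutations while T <= 7


@dataclass(frozen=True)
class ModelProfile:
    """A unit-change temporal template: integer values, first is 0."""

    profile_id: int
    values: tuple[int, ...]


@dataclass
class ProfileSet:
    """Selected model profiles plus the generation parameters."""

    profiles: list[ModelProfile]
    c: int  # maximum unit change per step
    m: int  # requested number of profiles

    def __len__(self) -> int:
        return len(self.profiles)

    @property
    def value_matrix(self) -> np.ndarray:
        return np.array([p.values for p in self.profiles], dtype=float)

    @property
    def flat_id(self) -> int:
        for p in self.profiles:
            if all(v == 0 for v in p.values):
                return p.profile_id
        raise ValueError("profile set lacks the flat profile")


@dataclass
class ProfileStats:
    """Permutation significance of one profile's assigned gene count."""

    profile_id: int
    observed: int
    expected_proportion: float
    p_value: float
    p_corrected: float
    significant: bool


@dataclass
class ClusterResult:
    """A group of correlated significant profiles and their genes."""

    cluster_id: int
    profile_ids: list[int]
    gene_ids: list
    path_id: int | None = None
    representative_profile: int | None = None


def log_ratio_transform(series: pd.DataFrame) -> pd.DataFrame:
    """Anchor each gene's series at its first sampled time point.

    Input values are already on an additive (log or slope) scale, so the
    log ratio against time point 1 is a plain subtraction; the first
    column becomes identically zero.
    """
    if series.shape[1] < 3:
        raise ValueError("need at least 3 sampled time points")
    return series.sub(series.iloc[:, 0], axis=0)


def generate_profiles(T: int, c: int) -> list[ModelProfile]:
    """All (2c+1)^(T-1) unit-step templates, lexicographic by values."""
    if T < 2:
        raise ValueError("profiles need at least 2 time points")
    if c < 1:
        raise ValueError("max unit change c must be >= 1")
    steps = range(-c, c + 1)
    values = sorted(
        tuple(itertools.accumulate((0,) + delta))
        for delta in itertools.product(steps, repeat=T - 1)
    )
    return [ModelProfile(i, v) for i, v in enumerate(values)]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _profile_distance(a: tuple, b: tuple) -> float:
    """1 - Pearson correlation; any pair involving a flat profile is 1."""
    av, bv = np.asarray(a, float), np.asarray(b, float)
    if av.std() == 0 or bv.std() == 0:
        return 1.0
    return 1.0 - _pearson(av, bv)


def select_profiles(
    candidates: list[ModelProfile], m: int, seed: int | None = None
) -> ProfileSet:
    """Greedy max-min selection of m distinct profiles.

    Starts from the flat profile and repeatedly adds the candidate whose
    minimum distance to the chosen set is largest; ties resolve to the
    lexicographically smallest value vector. Deterministic (the seed is
    accepted for interface symmetry but unused).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    c = max(
        (max(abs(v2 - v1) for v1, v2 in zip(p.values, p.values[1:])) or 1)
        for p in candidates
    )
    if m >= len(candidates):
        return ProfileSet(profiles=list(candidates), c=c, m=m)
    flat = next(p for p in candidates if all(v == 0 for v in p.values))
    chosen = [flat]
    chosen_keys = {flat.values}
    # distance from every candidate to the current chosen set
    min_dist = {
        p.values: _profile_distance(p.values, flat.values) for p in candidates
    }
    while len(chosen) < m:
        best = max(
            (p for p in candidates if p.values not in chosen_keys),
            key=lambda p: (min_dist[p.values], tuple(-v for v in p.values)),
        )
        chosen.append(best)
        chosen_keys.add(best.values)
        for p in candidates:
            if p.values in chosen_keys:
                continue
            d = _profile_distance(p.values, best.values)
            if d < min_dist[p.values]:
                min_dist[p.values] = d
    chosen.sort(key=lambda p: p.values)
    return ProfileSet(
        profiles=[ModelProfile(i, p.values) for i, p in enumerate(chosen)],
        c=c,
        m=m,
    )


def _standardize_rows(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows scaled to zero mean / unit norm; zero-variance rows zeroed."""
    centered = mat - mat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    flat = norms.ravel() == 0
    norms[flat.reshape(-1, 1)] = 1.0
    return centered / norms, flat


def _assign_matrix(
    series_values: np.ndarray, profile_set: ProfileSet
) -> np.ndarray:
    """Closest-profile index per row (1 - Pearson distance).

    Zero-variance genes go to the flat profile; correlation ties resolve
    to the lowest profile id (within 1e-12).
    """
    zp, prof_flat = _standardize_rows(profile_set.value_matrix)
    zg, gene_flat = _standardize_rows(series_values)
    corr = zg @ zp.T
    corr[:, prof_flat] = 0.0  # flat-vs-any distance convention: 1 - 0
    best = corr.max(axis=1, keepdims=True)
    choice = np.argmax(corr >= best - 1e-12, axis=1)
    choice[gene_flat] = profile_set.flat_id
    return choice


def assign_genes(
    series: pd.DataFrame, profile_set: ProfileSet
) -> tuple[pd.Series, np.ndarray]:
    """Assign every gene to exactly one profile.

    Returns the per-gene profile id and the per-profile observed counts
    (indexed by profile id).
    """
    choice = _assign_matrix(series.to_numpy(dtype=float), profile_set)
    counts = np.bincount(choice, minlength=len(profile_set))
    return pd.Series(choice, index=series.index, name="profile_id"), counts


def _permutations(T: int, n_perm: int, seed: int | None):
    """All T! column orders if cheap, else n_perm seeded draws."""
    if math.factorial(T) <= EXACT_PERMUTATION_LIMIT:
        return [np.array(p) for p in itertools.permutations(range(T))], True
    rng = np.random.default_rng(seed)
    return [rng.permutation(T) for _ in range(n_perm)], False


def permutation_significance(
    series: pd.DataFrame,
    profile_set: ProfileSet,
    observed_counts: np.ndarray,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int | None = None,
) -> list[ProfileStats]:
    """Binomial-tail significance of each profile's gene count.

    Every gene's time-point labels are permuted (exhaustively when
    T! <= 5040, else ``n_perm`` seeded samples) and re-assigned; the
    expected proportion p_k of profile k is its share of all
    gene x permutation assignments. The p-value is the upper binomial
    tail P(X >= observed) with X ~ Bin(n_genes, p_k), Bonferroni
    corrected across the profile set.
    """
    n_genes, T = series.shape
    if n_genes == 0:
        return []
    values = series.to_numpy(dtype=float)
    perms, _exact = _permutations(T, n_perm, seed)
    perm_counts = np.zeros(len(profile_set), dtype=np.int64)
    for perm in perms:
        choice = _assign_matrix(values[:, perm], profile_set)
        perm_counts += np.bincount(choice, minlength=len(profile_set))
    expected = perm_counts / (n_genes * len(perms))
    m = len(profile_set)
    stats = []
    for k, prof in enumerate(profile_set.profiles):
        obs = int(observed_counts[k])
        p = float(scipy.stats.binom.sf(obs - 1, n_genes, expected[k]))
        p_corr = min(1.0, p * m)
        stats.append(
            ProfileStats(
                profile_id=prof.profile_id,
                observed=obs,
                expected_proportion=float(expected[k]),
                p_value=p,
                p_corrected=p_corr,
                significant=p_corr <= alpha,
            )
        )
    return stats


def group_profiles(
    stats: list[ProfileStats],
    profile_set: ProfileSet,
    assignment: pd.Series,
    delta: float = 0.7,
    path_id: int | None = None,
) -> list[ClusterResult]:
    """Merge correlated significant profiles into clusters.

    Significant profiles are linked when their value vectors correlate
    at >= delta; clusters are the connected components (so linkage is
    transitive). Clusters are numbered by decreasing gene count, ties
    by lowest member profile id; each cluster's representative is its
    largest member profile.
    """
    if not 0 < delta <= 1:
        raise ValueError("delta must be in (0, 1]")
    sig = [s for s in stats if s.significant]
    if not sig:
        return []
    by_id = {p.profile_id: p for p in profile_set.profiles}
    g = nx.Graph()
    g.add_nodes_from(s.profile_id for s in sig)
    for a, b in itertools.combinations(sig, 2):
        va = np.asarray(by_id[a.profile_id].values, float)
        vb = np.asarray(by_id[b.profile_id].values, float)
        if va.std() == 0 or vb.std() == 0:
            continue
        if _pearson(va, vb) >= delta:
            g.add_edge(a.profile_id, b.profile_id)
    genes_by_profile = {
        pid: list(assignment.index[assignment == pid]) for pid in g.nodes
    }
    raw = []
    for comp in nx.connected_components(g):
        pids = sorted(comp)
        genes = sorted({gid for p in pids for gid in genes_by_profile[p]})
        rep = max(pids, key=lambda p: (len(genes_by_profile[p]), -p))
        raw.append((pids, genes, rep))
    raw.sort(key=lambda r: (-len(r[1]), r[0][0]))
    return [
        ClusterResult(
            cluster_id=i,
            profile_ids=pids,
            gene_ids=genes,
            path_id=path_id,
            representative_profile=rep,
        )
        for i, (pids, genes, rep) in enumerate(raw)
    ]


def cluster_path(
    series: pd.DataFrame,
    c: int = 2,
    m: int = 50,
    delta: float = 0.7,
    alpha: float = 0.05,
    n_perm: int = 500,
    seed: int | None = None,
    path_id: int | None = None,
) -> tuple[pd.Series, list[ProfileStats], list[ClusterResult]]:
    """Full engine for one path: transform, assign, test, group."""
    transformed = log_ratio_transform(series)
    T = transformed.shape[1]
    profile_set = select_profiles(generate_profiles(T, c), m, seed=seed)
    assignment, counts = assign_genes(transformed, profile_set)
    stats = permutation_significance(
        transformed, profile_set, counts, n_perm=n_perm, alpha=alpha, seed=seed
    )
    clusters = group_profiles(stats, profile_set, assignment, delta, path_id)
    return assignment, stats, clusters
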