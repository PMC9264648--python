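"""Trajectory-tree handling: rooting, path enumeration, segmentation.

A trajectory inferred by an external tool arrives as an undirected tree
of milestone nodes with cells placed fractionally along edges. This
module roots the tree from real capture times, walks every root-to-leaf
path, carves each path into key segments delimited by special milestones
(root / branching / leaf), and — when a path has fewer than three key
segments — subdivides segments at pseudotime quantiles so the downstream
profile clustering always sees at least three sampled time points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Placement",
    "TrajectoryGraph",
    "SampledTimePoint",
    "PathDef",
    "PathUnusableError",
    "select_root",
    "classify_milestones",
    "enumerate_paths",
    "pseudotime_per_cell",
    "key_segments",
    "subdivide",
]


@dataclass(frozen=True)
class Placement:
    """A cell's position: edge index plus fraction from the edge's 'from' node."""

    edge_index: int
    percentage: float


@dataclass
class TrajectoryGraph:
    """Undirected milestone tree with fractional cell placements."""

    milestones: list
    edges: list[tuple]  # (from, to, length)
    placements: dict[str, Placement]  # cell_id -> placement

    def __post_init__(self) -> None:
        g = nx.Graph()
        g.add_nodes_from(self.milestones)
        for u, v, length in self.edges:
            if u == v:
                raise ValueError(f"self-edge at milestone {u!r}")
            if u not in g or v not in g:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown milestone")
            if length <= 0:
                raise ValueError(f"edge ({u!r}, {v!r}) has non-positive length")
            g.add_edge(u, v)
        if len(self.milestones) > 1 and not nx.is_connected(g):
            raise ValueError("trajectory graph is disconnected; not a tree")
        if len(self.edges) != len(self.milestones) - 1:
            raise ValueError(
                f"not a tree: {len(self.edges)} edges for "
                f"{len(self.milestones)} milestones"
            )
        self._graph = g

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    def degree(self, milestone) -> int:
        return self._graph.degree[milestone]


@dataclass
class SampledTimePoint:
    """One aggregation unit on a path: a cell set over a pseudotime interval."""

    index: int  # ordinal within the path
    cell_ids: list[str]
    interval: tuple[float, float]  # [lo, hi) in pseudotime


@dataclass
class PathDef:
    """A root-to-leaf path with its key segments and sampled time points."""

    path_id: int
    milestones: list  # ordered root .. leaf
    edge_indices: list[int] = field(default_factory=list)
    segments: list[list[str]] = field(default_factory=list)  # cells per key segment
    segment_edges: list[list[int]] = field(default_factory=list)
    time_points: list[SampledTimePoint] = field(default_factory=list)

    @property
    def leaf(self):
        return self.milestones[-1]


class PathUnusableError(ValueError):
    """A path cannot be subdivided into usable sampled time points."""


def _edge_endpoint_depths(traj: TrajectoryGraph, root) -> dict:
    """Milestone -> summed edge length from root."""
    lengths = {(u, v): w for u, v, w in traj.edges}
    lengths.update({(v, u): w for u, v, w in traj.edges})
    depth = {root: 0.0}
    for u, v in nx.bfs_edges(traj.graph, root):
        depth[v] = depth[u] + lengths[(u, v)]
    return depth


def select_root(traj: TrajectoryGraph, cell_meta: pd.DataFrame):
    """Pick the milestone whose nearby cells were captured earliest.

    For each milestone, the capture times of cells placed on its incident
    edges are averaged with weight (1 - fractional distance from the cell
    to the milestone along its edge); the milestone with the smallest
    weighted mean wins. Ties (and the all-equal case) resolve to the
    smallest milestone id. Milestones with no cells on incident edges are
    not candidates.
    """
    if not traj.placements:
        raise ValueError("no placed cells; cannot select a root")
    capture = dict(
        zip(cell_meta["cell_id"], cell_meta["capture_time"].astype(float))
    )
    missing = [c for c in traj.placements if c not in capture]
    if missing:
        raise ValueError(
            f"placed cells lack capture_time (e.g. {missing[:5]})"
        )
    wsum: dict = {m: 0.0 for m in traj.milestones}
    tsum: dict = {m: 0.0 for m in traj.milestones}
    for cell, plc in traj.placements.items():
        u, v, _ = traj.edges[plc.edge_index]
        t = capture[cell]
        for node, frac in ((u, plc.percentage), (v, 1.0 - plc.percentage)):
            w = 1.0 - frac  # frac = distance fraction from cell to node
            wsum[node] += w
            tsum[node] += w * t
    candidates = [m for m in traj.milestones if wsum[m] > 0]
    if not candidates:
        raise ValueError("no milestone has positively weighted cells")
    return min(candidates, key=lambda m: (tsum[m] / wsum[m], str(m)))


def classify_milestones(traj: TrajectoryGraph, root) -> dict:
    """Label milestones as root / branching / leaf / internal.

    With the tree rooted, branching means >= 2 children (equivalently,
    undirected degree >= 3 off the root); leaves are degree-1 non-root
    nodes.
    """
    if root not in traj.graph:
        raise ValueError(f"root {root!r} is not a milestone")
    directed = nx.bfs_tree(traj.graph, root)
    roles = {}
    for m in traj.milestones:
        if m == root:
            roles[m] = "root"
        elif traj.degree(m) == 1:
            roles[m] = "leaf"
        elif directed.out_degree(m) >= 2:
            roles[m] = "branching"
        else:
            roles[m] = "internal"
    return roles


def enumerate_paths(traj: TrajectoryGraph, root) -> list[PathDef]:
    """One PathDef per leaf, ordered by leaf id, numbered from 0."""
    roles = classify_milestones(traj, root)
    leaves = sorted((m for m, r in roles.items() if r == "leaf"), key=str)
    if not leaves:
        warnings.warn("root is the only milestone; no paths")
        return []
    edge_lookup = {}
    for i, (u, v, _) in enumerate(traj.edges):
        edge_lookup[(u, v)] = i
        edge_lookup[(v, u)] = i
    paths = []
    for pid, leaf in enumerate(leaves):
        nodes = nx.shortest_path(traj.graph, root, leaf)
        eidx = [edge_lookup[(nodes[i], nodes[i + 1])] for i in range(len(nodes) - 1)]
        paths.append(PathDef(path_id=pid, milestones=nodes, edge_indices=eidx))
    return paths


def pseudotime_per_cell(traj: TrajectoryGraph, root) -> dict[str, float]:
    """Distance from the root to each placed cell along the tree.

    pseudotime = depth of the edge's root-proximal endpoint plus the
    cell's fractional offset from that endpoint times the edge length.
    """
    depth = _edge_endpoint_depths(traj, root)
    pt = {}
    for cell, plc in traj.placements.items():
        u, v, length = traj.edges[plc.edge_index]
        if depth[u] <= depth[v]:
            frac_from_proximal = plc.percentage
            proximal = u
        else:
            frac_from_proximal = 1.0 - plc.percentage
            proximal = v
        pt[cell] = depth[proximal] + frac_from_proximal * length
    return pt


def key_segments(traj: TrajectoryGraph, path: PathDef, roles: dict) -> PathDef:
    """Split a path at its special milestones and bucket cells by edge.

    Key milestones are the path's root, branching nodes and leaf; each
    consecutive pair delimits one segment. Every path edge lands in
    exactly one segment; cells go to the segment containing their
    placement edge.
    """
    key_positions = [
        i
        for i, m in enumerate(path.milestones)
        if roles[m] in ("root", "branching", "leaf")
    ]
    cells_by_edge: dict[int, list[str]] = {}
    for cell, plc in traj.placements.items():
        cells_by_edge.setdefault(plc.edge_index, []).append(cell)
    segments, segment_edges = [], []
    for a, b in zip(key_positions[:-1], key_positions[1:]):
        edges = path.edge_indices[a:b]
        cells: list[str] = []
        for e in edges:
            cells.extend(cells_by_edge.get(e, []))
        segments.append(sorted(cells))
        segment_edges.append(edges)
    path.segments = segments
    path.segment_edges = segment_edges
    return path


def _lower_quantile_cut(sorted_pt: np.ndarray, fraction: float) -> float:
    """Lower empirical quantile: value at index ceil(n*fraction) - 1."""
    n = len(sorted_pt)
    idx = max(int(np.ceil(n * fraction)) - 1, 0)
    return float(sorted_pt[idx])


def _split_cells(
    cells: list[str], pt: dict[str, float], fractions: list[float]
) -> list[list[str]]:
    """Partition cells at lower-quantile cuts; boundary ties go earlier."""
    order = sorted(cells, key=lambda c: (pt[c], c))
    sorted_pt = np.array([pt[c] for c in order])
    cuts = [_lower_quantile_cut(sorted_pt, f) for f in fractions]
    groups: list[list[str]] = [[] for _ in range(len(fractions) + 1)]
    for c in order:
        for gi, cut in enumerate(cuts):
            if pt[c] <= cut:
                groups[gi].append(c)
                break
        else:
            groups[-1].append(c)
    return groups


def subdivide(
    path: PathDef, pseudotime: dict[str, float], min_cells: int = 3
) -> PathDef:
    """Ensure a path has >= 3 sampled time points.

    With >= 3 key segments the segments are used as-is. A single key
    segment is cut at the lower 1/3 and 2/3 pseudotime quantiles of its
    cells (3 time points); two key segments are each cut at their cells'
    median (4 time points). Quantiles use the lower empirical convention
    and cells exactly at a cut go to the earlier time point.
    """
    if not path.segments:
        raise ValueError("path has no key segments; call key_segments first")
    n_seg = len(path.segments)
    if n_seg >= 3:
        groups = [list(s) for s in path.segments]
    else:
        for seg in path.segments:
            if len(seg) < min_cells:
                raise PathUnusableError(
                    f"path {path.path_id}: key segment with {len(seg)} cells "
                    f"(< {min_cells}) cannot be subdivided"
                )
        if n_seg == 1:
            groups = _split_cells(path.segments[0], pseudotime, [1 / 3, 2 / 3])
        else:  # two segments, median split each
            groups = []
            for seg in path.segments:
                groups.extend(_split_cells(seg, pseudotime, [0.5]))
    tps = []
    for i, cells in enumerate(groups):
        if not cells:
            raise PathUnusableError(
                f"path {path.path_id}: sampled time point {i} is empty"
            )
        vals = [pseudotime[c] for c in cells]
        tps.append(
            SampledTimePoint(index=i, cell_ids=cells, interval=(min(vals), max(vals)))
        )
    order = np.argsort([tp.interval[0] for tp in tps], kind="stable")
    tps = [tps[i] for i in order]
    for i, tp in enumerate(tps):
        tp.index = i
    path.time_points = tps
    return path
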