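import networkx as nx
import numpy as np
import pandas as pd
import pytest

import stempath as stp
from stempath.trajectory import PathUnusableError


def meta_frame(times: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {"cell_id": list(times), "capture_time": list(times.values())}
    )


def random_trajectory(n_nodes, seed, cells_per_edge=0):
    """Random labeled tree wrapped as a TrajectoryGraph."""
    rng = np.random.default_rng(seed)
    tree = nx.random_labeled_tree(n_nodes, seed=int(rng.integers(2**31)))
    milestones = [f"N{i:03d}" for i in tree.nodes]
    edges = [(f"N{u:03d}", f"N{v:03d}", 1.0) for u, v in tree.edges]
    placements = {}
    k = 0
    for ei in range(len(edges)):
        for _ in range(cells_per_edge):
            placements[f"c{k:05d}"] = stp.Placement(ei, float(rng.uniform()))
            k += 1
    return stp.TrajectoryGraph(
        milestones=milestones, edges=edges, placements=placements
    )


class TestSelectRoot:
    def test_monotone_capture_times_give_early_end(self, chain_trajectory):
        times = {"c0": 1, "c1": 1, "c2": 2, "c3": 2, "c4": 3, "c5": 3}
        assert stp.select_root(chain_trajectory, meta_frame(times)) == "A"

    def test_all_equal_times_tie_break_lexicographic(self, chain_trajectory):
        times = {c: 5.0 for c in chain_trajectory.placements}
        assert stp.select_root(chain_trajectory, meta_frame(times)) == "A"

    def test_matches_exhaustive_weighted_mean_oracle(self):
        traj = random_trajectory(5, seed=3, cells_per_edge=4)
        rng = np.random.default_rng(7)
        times = {c: float(rng.uniform(0, 10)) for c in traj.placements}
        # oracle: evaluate the weighted mean at every milestone explicitly
        best, best_key = None, None
        for m in traj.milestones:
            num = den = 0.0
            for cell, plc in traj.placements.items():
                u, v, _ = traj.edges[plc.edge_index]
                if m == u:
                    w = 1.0 - plc.percentage
                elif m == v:
                    w = plc.percentage
                else:
                    continue
                num += w * times[cell]
                den += w
            if den > 0 and (best_key is None or (num / den, m) < best_key):
                best_key, best = (num / den, m), m
        assert stp.select_root(traj, meta_frame(times)) == best

    def test_no_cells_errors(self):
        traj = random_trajectory(4, seed=0, cells_per_edge=0)
        with pytest.raises(ValueError, match="no placed cells"):
            stp.select_root(traj, meta_frame({}))


class TestClassifyMilestones:
    def test_chain_roles(self, chain_trajectory):
        roles = stp.classify_milestones(chain_trajectory, "A")
        assert roles == {"A": "root", "B": "internal", "C": "leaf"}

    def test_degree_three_center_is_branching(self):
        traj = stp.TrajectoryGraph(
            milestones=["X", "A", "B", "C"],
            edges=[("X", "A", 1.0), ("X", "B", 1.0), ("X", "C", 1.0)],
            placements={},
        )
        assert stp.classify_milestones(traj, "A")["X"] == "branching"

    def test_two_children_is_branching(self):
        traj = stp.TrajectoryGraph(
            milestones=["R", "M", "L1", "L2"],
            edges=[("R", "M", 1.0), ("M", "L1", 1.0), ("M", "L2", 1.0)],
            placements={},
        )
        assert stp.classify_milestones(traj, "R")["M"] == "branching"


class TestEnumeratePaths:
    def test_chain_has_one_path(self, chain_trajectory):
        paths = stp.enumerate_paths(chain_trajectory, "A")
        assert len(paths) == 1
        assert paths[0].milestones == ["A", "B", "C"]

    def test_balanced_binary_tree_has_four_paths(self):
        edges = [
            ("R", "L", 1.0), ("R", "Rt", 1.0),
            ("L", "L1", 1.0), ("L", "L2", 1.0),
            ("Rt", "R1", 1.0), ("Rt", "R2", 1.0),
        ]
        traj = stp.TrajectoryGraph(
            milestones=["R", "L", "Rt", "L1", "L2", "R1", "R2"],
            edges=edges,
            placements={},
        )
        paths = stp.enumerate_paths(traj, "R")
        assert len(paths) == 4
        assert [p.path_id for p in paths] == [0, 1, 2, 3]

    def test_random_tree_path_count_equals_leaf_count(self):
        traj = random_trajectory(50, seed=11)
        root = traj.milestones[0]
        paths = stp.enumerate_paths(traj, root)
        # oracle: count degree-1 non-root nodes directly
        n_leaves = sum(
            1 for m in traj.milestones if m != root and traj.degree(m) == 1
        )
        assert len(paths) == n_leaves

    def test_singleton_tree_warns_empty(self):
        traj = stp.TrajectoryGraph(milestones=["A"], edges=[], placements={})
        with pytest.warns(UserWarning):
            assert stp.enumerate_paths(traj, "A") == []


class TestPseudotime:
    def test_cell_at_root_is_zero(self, chain_trajectory):
        pt = stp.pseudotime_per_cell(chain_trajectory, "A")
        assert pt["c0"] == 0.0

    def test_depth_plus_offset(self):
        traj = stp.TrajectoryGraph(
            milestones=["A", "B", "C"],
            edges=[("A", "B", 1.0), ("B", "C", 2.0)],
            placements={"x": stp.Placement(1, 0.5)},
        )
        assert stp.pseudotime_per_cell(traj, "A")["x"] == pytest.approx(2.0)

    def test_reversed_edge_orientation_handled(self):
        # edge stored leaf -> root; percentage is measured from 'from'
        traj = stp.TrajectoryGraph(
            milestones=["A", "B"],
            edges=[("B", "A", 2.0)],
            placements={"x": stp.Placement(0, 0.75)},
        )
        # x is 25% of the way from A (the root) toward B
        assert stp.pseudotime_per_cell(traj, "A")["x"] == pytest.approx(0.5)

    def test_matches_explicit_root_walk(self):
        traj = random_trajectory(12, seed=5, cells_per_edge=2)
        root = traj.milestones[0]
        pt = stp.pseudotime_per_cell(traj, root)
        lengths = {}
        for u, v, w in traj.edges:
            lengths[(u, v)] = lengths[(v, u)] = w
        g = traj.graph
        for cell, plc in traj.placements.items():
            u, v, w = traj.edges[plc.edge_index]
            du = nx.shortest_path_length(g, root, u, weight=None)
            dv = nx.shortest_path_length(g, root, v, weight=None)
            # oracle: walk the explicit root path, summing lengths
            proximal, distal = (u, v) if du < dv else (v, u)
            frac = plc.percentage if proximal == u else 1 - plc.percentage
            walk = nx.shortest_path(g, root, proximal)
            dist = sum(lengths[(a, b)] for a, b in zip(walk, walk[1:]))
            assert pt[cell] == pytest.approx(dist + frac * w)


def build_path(traj, root):
    roles = stp.classify_milestones(traj, root)
    paths = stp.enumerate_paths(traj, root)
    return [stp.key_segments(traj, p, roles) for p in paths], roles


class TestKeySegments:
    def test_chain_is_single_segment(self, chain_trajectory):
        paths, _ = build_path(chain_trajectory, "A")
        assert len(paths[0].segments) == 1
        assert sorted(paths[0].segments[0]) == sorted(chain_trajectory.placements)

    def test_one_branching_node_gives_two_segments(self):
        traj = stp.TrajectoryGraph(
            milestones=["R", "M", "L1", "L2"],
            edges=[("R", "M", 1.0), ("M", "L1", 1.0), ("M", "L2", 1.0)],
            placements={"a": stp.Placement(0, 0.5), "b": stp.Placement(1, 0.5)},
        )
        paths, _ = build_path(traj, "R")
        assert [len(p.segments) for p in paths] == [2, 2]
        assert paths[0].segments == [["a"], ["b"]]

    def test_three_branchings_give_four_segments(self):
        # caterpillar: spine R-B1-B2-B3-L with a leaf at every spine node
        edges = [
            ("R", "B1", 1.0), ("B1", "B2", 1.0), ("B2", "B3", 1.0),
            ("B3", "L", 1.0), ("B1", "X1", 1.0), ("B2", "X2", 1.0),
            ("B3", "X3", 1.0),
        ]
        traj = stp.TrajectoryGraph(
            milestones=["R", "B1", "B2", "B3", "L", "X1", "X2", "X3"],
            edges=edges,
            placements={},
        )
        paths, roles = build_path(traj, "R")
        spine = next(p for p in paths if p.leaf == "L")
        # oracle: scan of roles along the spine
        key_count = sum(
            1 for m in spine.milestones if roles[m] in ("root", "branching", "leaf")
        )
        assert len(spine.segments) == key_count - 1 == 4


class TestSubdivide:
    def _chain_with_cells(self, pts):
        placements = {
            f"c{i}": stp.Placement(0, p / max(pts)) for i, p in enumerate(pts)
        }
        traj = stp.TrajectoryGraph(
            milestones=["A", "B"],
            edges=[("A", "B", float(max(pts)))],
            placements=placements,
        )
        paths, _ = build_path(traj, "A")
        return traj, paths[0]

    def test_three_segments_unchanged(self):
        edges = [
            ("R", "B1", 1.0), ("B1", "B2", 1.0), ("B2", "L", 1.0),
            ("B1", "X1", 1.0), ("B2", "X2", 1.0),
        ]
        placements = {
            f"c{i}": stp.Placement(i % 3, 0.5 + 0.1 * (i // 3)) for i in range(9)
        }
        traj = stp.TrajectoryGraph(
            milestones=["R", "B1", "B2", "L", "X1", "X2"],
            edges=edges,
            placements=placements,
        )
        paths, roles = build_path(traj, "R")
        spine = next(p for p in paths if p.leaf == "L")
        pt = stp.pseudotime_per_cell(traj, "R")
        stp.subdivide(spine, pt)
        assert [tp.cell_ids for tp in spine.time_points] == spine.segments

    def test_single_segment_thirds_at_lower_quantiles(self):
        traj, path = self._chain_with_cells(list(range(1, 10)))
        pt = stp.pseudotime_per_cell(traj, "A")
        stp.subdivide(path, pt)
        groups = [sorted(tp.cell_ids) for tp in path.time_points]
        assert groups == [
            ["c0", "c1", "c2"],  # pseudotimes 1..3
            ["c3", "c4", "c5"],  # 4..6
            ["c6", "c7", "c8"],  # 7..9
        ]

    def test_two_segments_median_split(self):
        traj = stp.TrajectoryGraph(
            milestones=["R", "M", "L1", "L2"],
            edges=[("R", "M", 1.0), ("M", "L1", 1.0), ("M", "L2", 1.0)],
            placements={
                **{f"a{i}": stp.Placement(0, 0.2 * (i + 1)) for i in range(4)},
                **{f"b{i}": stp.Placement(1, 0.2 * (i + 1)) for i in range(4)},
            },
        )
        paths, roles = build_path(traj, "R")
        pt = stp.pseudotime_per_cell(traj, "R")
        stp.subdivide(paths[0], pt)
        assert [len(tp.cell_ids) for tp in paths[0].time_points] == [2, 2, 2, 2]

    def test_boundary_ties_go_to_earlier_time_point(self):
        traj, path = self._chain_with_cells([1, 2, 2, 2, 5, 6, 7, 8, 9])
        pt = stp.pseudotime_per_cell(traj, "A")
        stp.subdivide(path, pt)
        # lower 1/3 quantile is 2; all three cells at 2 go to the first group
        assert sorted(path.time_points[0].cell_ids) == ["c0", "c1", "c2", "c3"]

    def test_small_segment_flags_path_unusable(self):
        traj, path = self._chain_with_cells([1, 2])
        pt = stp.pseudotime_per_cell(traj, "A")
        with pytest.raises(PathUnusableError):
            stp.subdivide(path, pt)

    def test_never_fewer_than_three_time_points_and_partition(self):
        for seed in range(5):
            traj = random_trajectory(15, seed=seed, cells_per_edge=6)
            root = traj.milestones[0]
            roles = stp.classify_milestones(traj, root)
            pt = stp.pseudotime_per_cell(traj, root)
            for path in stp.enumerate_paths(traj, root):
                stp.key_segments(traj, path, roles)
                try:
                    stp.subdivide(path, pt)
                except PathUnusableError:
                    continue
                assert len(path.time_points) >= 3
                on_path = {
                    c
                    for c, plc in traj.placements.items()
                    if plc.edge_index in set(path.edge_indices)
                }
                tp_cells = [set(tp.cell_ids) for tp in path.time_points]
                assert set().union(*tp_cells) == on_path
                assert sum(len(s) for s in tp_cells) == len(on_path)
                # pseudotime increases across ordered time points
                maxima = [max(pt[c] for c in s) for s in tp_cells]
                minima = [min(pt[c] for c in s) for s in tp_cells]
                assert all(a <= b for a, b in zip(maxima, minima[1:]))
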