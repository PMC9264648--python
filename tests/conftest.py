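import numpy as np
import pytest
import scipy.sparse as sp

import stempath as stp


@pytest.fixture
def toy_counts():
    """3 genes x 3 cells with one sparse gene and one sparse cell."""
    mat = np.array(
        [
            [3, 0, 2],
            [0, 0, 1],  # expressed in 1 cell only
            [4, 5, 0],
        ]
    )
    return stp.CountMatrix(
        gene_ids=np.array(["G1", "G2", "G3"], dtype=object),
        cell_ids=np.array(["C1", "C2", "C3"], dtype=object),
        counts=sp.csr_matrix(mat),
    )


@pytest.fixture
def chain_trajectory():
    """Linear tree A-B-C with three cells per edge."""
    placements = {
        "c0": stp.Placement(0, 0.0),
        "c1": stp.Placement(0, 0.5),
        "c2": stp.Placement(0, 0.9),
        "c3": stp.Placement(1, 0.1),
        "c4": stp.Placement(1, 0.5),
        "c5": stp.Placement(1, 0.8),
    }
    return stp.TrajectoryGraph(
        milestones=["A", "B", "C"],
        edges=[("A", "B", 1.0), ("B", "C", 1.0)],
        placements=placements,
    )


@pytest.fixture(scope="session")
def standard_fixture():
    """The default planted-program study: 100 up, 100 down, 800 flat
    genes on a 2-leaf tree with 400 cells per edge, seed 0."""
    traj, meta = stp.simulate_trajectory(n_leaves=2, cells_per_edge=400, seed=0)
    programs = [
        stp.ProgramSpec("up", 0, 100),
        stp.ProgramSpec("down", 0, 100),
        stp.ProgramSpec("flat", 0, 800),
    ]
    counts, truth = stp.simulate_counts(traj, programs, seed=0)
    return traj, meta, counts, truth


@pytest.fixture(scope="session")
def standard_clustering(standard_fixture):
    """Mean-metric clustering of path 0 of the standard fixture."""
    traj, meta, counts, truth = standard_fixture
    root, pt, paths, _ = stp.prepare_paths(traj, meta)
    norm = stp.log_normalize(counts)
    series = stp.build_series(paths[0], counts, norm, "mean", pseudotime=pt)
    assignment, stats, clusters = stp.cluster_path(series, seed=0, path_id=0)
    return truth, assignment, stats, clusters
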