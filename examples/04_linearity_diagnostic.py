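"""Check the linear-expression-change assumption on one trajectory edge.

The clustering model assumes a gene's expression changes roughly
linearly along each edge between milestones. This diagnostic fits
expression ~ pseudotime per gene within an edge, F-tests the slope and
BH-corrects, reporting how many genes show a significant linear trend.
"""

import stempath as stp

traj, cell_meta = stp.simulate_trajectory(n_leaves=1, cells_per_edge=200, seed=2)
programs = [
    stp.ProgramSpec("up", path_id=0, n_genes=50, effect_size=1.5),
    stp.ProgramSpec("flat", path_id=0, n_genes=450),
]
counts, truth = stp.simulate_counts(traj, programs, seed=2)
root, pseudotime, paths, _ = stp.prepare_paths(traj, cell_meta)
normalized = stp.log_normalize(counts)

path = paths[0]
for edge_index in path.edge_indices:
    edge_cells = sorted(
        c for c, p in traj.placements.items() if p.edge_index == edge_index
    )
    table = stp.linearity_diagnostic(edge_cells, normalized, pseudotime)
    n_sig = int((table.p_adjusted <= 0.05).sum())
    up_sig = table.loc[table.index.isin(
        truth.gene_id[truth.program == "up"])]
    print(
        f"edge {edge_index}: {len(table)} genes tested, "
        f"{n_sig} with BH-significant linear fit "
        f"(median up-gene slope {up_sig.slope.median():.3f})"
    )
# Planted up-genes dominate the significant fits with positive slopes;
# unchanged genes fit the intercept-only model and survive correction
# only at roughly the false-discovery rate.
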