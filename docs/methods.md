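# Methods

## Model and pipeline

`stempath` clusters genes by the shape of their expression along
individual root-to-leaf paths of a trajectory tree. The working
assumption is that a gene's expression changes roughly linearly along
each edge between milestone states, so a path can be compressed to a
short series — one summary value per *sampled time point* — without
losing the pattern that matters for clustering.

**Input contract.** Counts are genes × cells sparse nonnegative
integers (Matrix Market + id TSVs). The trajectory is a tree: milestone
nodes, weighted undirected edges, and per-cell placements as (edge,
fraction along the edge). Trajectory inference itself is out of scope;
any tool that emits a tree can feed the JSON schema in
`stempath.io.read_trajectory`.

**Preprocessing.** Genes expressed in fewer than `min_cells_per_gene`
(default 10) cells are dropped, then cells expressing fewer than
`min_genes_per_cell` (default 200) retained genes; each pass runs once,
genes first — the order matters only in edge cases and is fixed for
determinism. Log normalization uses size factors
`s_j = total_j / median(totals)` and values `ln(count/s_j + 1)`; the
exact constants of upstream tools vary, so the convention is explicit
and configurable. Optional variable-gene selection ranks genes by the
variance of log-normalized expression (a deliberate simplification of
vst-style selection; ties break on gene id). Normalization precedes
selection.

**Rooting.** The root is the milestone minimizing the proximity-
weighted mean capture time of cells on its incident edges, each cell
weighted by one minus its fractional distance to the milestone. This
concretizes "earliest real-time cells sit at the origin" without
requiring annotated start cells; milestones with no adjacent cells are
not candidates, and ties resolve to the smallest milestone id.

**Paths and time points.** One path per leaf, numbered in leaf-id
order. Key milestones (root, branching — ≥ 2 children once rooted —
and leaf) delimit key segments; cells belong to the segment holding
their placement edge. Paths with ≥ 3 key segments use them directly as
sampled time points. One-segment paths are cut at the lower empirical
1/3 and 2/3 pseudotime quantiles (3 time points); two-segment paths at
each segment's median (4 time points). Boundary cells go to the earlier
time point — deterministic and order-independent. A segment with fewer
than 3 cells when subdivision is needed makes the path unusable
(skipped with a warning); the threshold is a floor for a meaningful
quantile split, not a tuned constant. Cells on edges shared by several
paths contribute to every such path, since paths are clustered
independently.

## Summary metrics

* **mean** — arithmetic mean of log-normalized expression per time
  point. The default; sensitive to homogeneous shifts in expression
  level.
* **entropy** — `ds = ln(mean(X+1)) − mean(ln(X+1))` on raw counts,
  per gene per time point. The gap between the log of the mean and the
  mean of the logs is zero exactly when all cells agree and grows with
  expression heterogeneity (Jensen). The population expectation is
  estimated by the sample mean rather than a fitted Poisson-Gamma
  model (no fitting procedure is uniquely implied; the estimator is
  isolated so a model-based one can be swapped in). A pseudocount of 1
  inside both logarithms keeps the score defined at zero counts while
  preserving nonnegativity and the zero-on-constant property.
* **rate** — per time point, cells with expression |Z| > 1.96 are
  removed (a dropout/outlier guard; the filter keeps the central 95%
  band), then OLS of log-normalized expression on pseudotime gives the
  slope. Degenerate fits (< 2 retained cells, or no pseudotime spread)
  report slope 0 with a flag so every gene yields a complete series —
  the clustering engine needs rectangular input.

**Which metric sees what.** The three metrics are sensitive to
different signals, and this matters for interpreting both real runs and
the synthetic benchmarks. A homogeneous log-linear program (every cell
shifts its mean) is a *mean*-metric signal. Its entropy trace is weak:
for negative-binomial counts with dispersion α,
`ds ≈ μ(1+αμ)/(2(1+μ)²)`, which grows with μ only at low expression and
saturates near α/2 — so entropy primarily detects changes in
*heterogeneity* (e.g. a program switching on in a growing subpopulation),
not level shifts. A log-linear program likewise has *constant* change
rate along the path, making it flat in rate space; the rate metric
responds to accelerating, decelerating or segment-restricted programs.
Consequently the planted-recovery guarantees below are stated for the
mean metric, and the entropy/rate pipelines are verified for
correctness and determinism rather than recovery of level-shift
programs.

## Profile clustering

Series are anchored by subtracting the first time point (values are
already on an additive log/slope scale, so the "log ratio" is a
subtraction; column 1 becomes 0). All `(2c+1)^(T−1)` candidate profiles
— integer sequences from 0 with steps in [−c, c] — are enumerated in
lexicographic order; `m` distinct ones are chosen greedily by
max-min distance (1 − Pearson; any pair involving the always-included
flat profile has distance 1), ties lexicographic. Assignment minimizes
1 − Pearson between a gene's anchored series and the profile values;
zero-variance genes go to the flat profile, correlation ties to the
lowest profile id.

Significance: each gene's time-point labels are permuted — all T!
permutations when T! ≤ 5040 (T ≤ 7), otherwise `n_perm` seeded draws —
and re-assigned. Because Pearson correlation is shift-invariant,
permuting the anchored series equals permuting the raw series and
re-anchoring. Profile k's expected proportion p_k is its share of all
gene × permutation assignments; its p-value is the upper binomial tail
P(Bin(n_genes, p_k) ≥ observed), Bonferroni-corrected over the m
profiles (α default 0.05). Significant profiles are linked when their
value vectors correlate at ≥ δ (default 0.7) and clusters are the
connected components, numbered by decreasing gene count.

Defaults c = 2, m = 50, δ = 0.7, n_perm = 500 are package choices in
the spirit of short-time-series profile clustering, not uniquely
mandated values; all are exposed.

## Hypergeometric machinery

`hypergeom_upper(k, K, n, N)` sums the exact log-pmf with logsumexp, so
tails far beyond double-underflow of naive summation remain accurate.
Cross-path comparison tests every cluster pair over the intersection of
the two runs' gene universes (genes outside it are excluded from all
counts), BH-corrected across pairs. Gene-set enrichment restricts each
set to the user-supplied background, reports fold enrichment
`(k/n)/(K/N)`, and ranks by fold (matching how enriched-term lists are
usually summarized) with a p-ranked option. Marker enrichment takes the
background as a plain size because marker validations typically use a
genome-wide universe larger than the loaded matrix. BH is applied
uniformly to these tables; Bonferroni is reserved for the profile
tests.

## Synthetic data

The generator emulates the study design end to end: a random binary-ish
tree (leaves split until the requested count), cells uniform along
edges, capture times discretized into 5 pseudotime-quantile bins (so
rooting from real time is recoverable and exercised), and
negative-binomial UMI counts, var = μ(1 + αμ), Poisson at α = 0.

Planted programs modulate the per-gene log-mean along one target path
(position s ∈ [0, 1]): up `f = β·s`, down `f = β·(1−s)` (elevated start
decaying to baseline, so counts never vanish), transient
`f = β·(1−|2s−1|)` (mid-path peak), flat 0. Defaults: baseline mean 5
UMI (a moderately expressed gene — the regime that survives variable-
gene selection), effect β = 1 natural log (~2.7-fold, a strong but
realistic program), dispersion α = 0.3. The standard benchmark fixture
is 1,000 genes × ~1,200 cells (400 cells/edge on a 2-leaf tree): 100
up, 100 down, 800 flat genes.

**What the generator does not emulate.** Cells are homogeneous within a
pseudotime position (no bimodal on/off mixtures), there is no batch
structure, no per-cell depth variation beyond the program-induced one,
and no dropout process beyond NB sampling. Passing the recovery
benchmarks therefore shows the pipeline recovers coherent level-shift
programs against NB noise — not that it handles batch effects or
zero-inflation.

**Known limitation: composition drift.** Total-count size factors make
normalized values of unchanged genes drift opposite to the summed
change of program genes. With ≤ ~20% of genes at ≤ ~e-fold change the
drift stays within noise; with implausibly strong planted programs it
can surface as a spurious low-amplitude cluster of unchanged genes — a
real property of library-size normalization, visible here because the
simulated transcriptome is small.

## Numerical choices

* Quantile subdivision uses the lower empirical quantile
  (`sorted[ceil(n·q)−1]`) with ties to the earlier time point.
* Correlation ties in assignment are resolved within 1e-12 toward the
  lowest profile id, keeping vectorized and scalar routes consistent.
* Perfect linear fits in the F-test diagnostic underflow; p-values are
  floored at the smallest positive double and flagged as such in tests.
* Exhaustive permutation enumeration makes significance seed-invariant
  whenever T ≤ 7; sampled permutation uses a single seeded generator.
* The genes-expressed-in-≥5%-of-cells filter for the linearity
  diagnostic, and the ≥ 3 cells/segment floor, are applied before any
  model fit, never after seeing results.

## Limitations

* Trajectories must be trees; cycles and disconnected graphs are
  rejected rather than repaired.
* The entropy metric's Poisson-Gamma expectation is approximated by
  the sample mean (see above).
* Cluster significance inherits the binomial approximation of treating
  genes as independent draws; co-expressed gene modules violate this,
  as they do in any profile-counting scheme.
* Cross-path overlap tests condition on the universe intersection;
  whether the proper universe is all input genes or clustered genes is
  a design choice, made explicit rather than hidden.
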