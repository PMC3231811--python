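# Methods

This note documents the models, the numerical choices, and the synthetic
benchmarks behind `bicgrn`, including the design decisions that were
genuinely open and the known limitations of the procedures implemented.

## Preprocessing

**KNN imputation** follows the gene-wise scheme standard for microarray
data: the distance between two gene rows is the mean squared difference
over their mutually observed conditions (so rows sharing few conditions are
not unfairly favoured), and a missing cell is replaced by the unweighted
mean of the *k* nearest rows observed in that condition (default *k* = 10).
If fewer than *k* eligible neighbours exist, all are used and a warning is
emitted; a gene with no observed value at all is an error, since no
neighbourhood is defined. Imputation is idempotent and never alters an
observed entry.

**Gene filtration** removes genes whose observed-value variance falls below
a threshold or whose missing fraction exceeds a cap. Both default to "off"
(threshold 0, cap 1) so that filtering is always an explicit analysis
decision rather than a silent one.

**Discretization** is per-gene equal-frequency binning into `levels` states
(default 3, the conventional under/base/over-expressed coding for log-ratio
data). Ties share the lower bin, so a constant gene maps to state 0 and the
output is invariant under strictly monotone per-gene transforms. Three
levels on *n* conditions means each parent configuration of a Bayesian
family sees roughly *n*/3<sup>p</sup> samples; a warning is emitted when a
bicluster has fewer than 3 × levels conditions.

## Biclustering

**Cheng–Church.** The mean squared residue
H(I,J) = mean over the submatrix of (x_ij − x_iJ − x_Ij + x_IJ)² is zero
exactly for constant and additive (row effect + column effect) patterns.
Extraction runs multiple-node deletion (drop rows/columns whose mean
residue exceeds α·H, α = 1.2 by default), then single-node deletion down to
H ≤ δ, then node addition of any row/column whose mean residue does not
exceed the current H; because means shift during addition a final deletion
pass guarantees the returned score really is ≤ δ. Extracted cells are
masked with uniform random values over the matrix's observed range
(seeded), the original device for making successive biclusters distinct.

*Limitation (important for benchmark design):* an additive-coherent block
embedded in a **corner** of a larger matrix is not additive relative to the
whole matrix — its cells are the global fit's worst outliers — so deletion
removes an embedded block first rather than last. Moreover any Gaussian
background of the same noise level is itself additive-coherent
(H ≈ σ²), so no δ separates "block" from "noise subset" when the block
merely overlays the same noise. The regime in which Cheng–Church provably
recovers a planted structure is a block of additive **rows spanning all
conditions** whose column effects the background rows misfit, with
within-block noise satisfying σ² ≲ δ. The recovery benchmark therefore
plants 30 additive rows across all 20 conditions at σ = 0.5 with δ = 0.5;
recovery there is exact (Jaccard 1.0 across seeds).

**ISA.** Condition scores are means of row-standardized expression over the
current gene set; gene scores are means of column-standardized expression
over the kept conditions. Scores are converted to z-values by multiplying
by √(set size) — the standard-error scaling, since standardized entries
have unit variance — so the thresholds t_g = t_c = 2.0 read as "two
standard errors". Seeds are uniform random 5-gene subsets; iteration stops
at a fixed point of the gene set (cap 50 iterations); converged modules
with gene-set Jaccard ≥ 0.9 are deduplicated keeping the first.

The default signature `direction="up"` keeps only positively scoring genes
and conditions. The two-sided alternative (`"updown"`) has a structural
artifact worth knowing about: a genuine up-module inflates the column means
that every other gene is standardized against, parking background genes
near z ≈ −1.8; at t = 2 the noise tail then admits a few anti-correlated
extras into almost every module (measured best-case Jaccard 0.65–0.83
against planted modules across matrix geometries). One-sided thresholding
removes the artifact and recovers planted up-modules exactly; down-modules
require running on the negated matrix.

**OPSM.** A model is an ordered column tuple; a row supports it when its
values strictly increase along the order, with ties broken by column index
(formally, comparison on (value, column) pairs — for continuous data this
is plain strict increase). All ordered pairs seed size 2; each round keeps
the `l_models` best models (support, then lexicographic order), extends
each by inserting one unused column at any position, and records the best
model per size while any model keeps ≥ 2 supporting rows. One bicluster per
recorded size is returned, largest support first. On matrices ≤ 5×5 the
top support equals exhaustive enumeration over all column-subset orderings.

**k-means** delegates to Lloyd's algorithm (scikit-learn, Euclidean,
`n_replicates` seeded restarts keeping the best within-cluster sum of
squares); each non-empty cluster becomes a bicluster over **all**
conditions, reflecting that traditional clustering performs no condition
selection.

## Enrichment comparison

The test statistic is the one-sided hypergeometric upper tail P(X ≥ k) —
the standard behind bicluster GO-enrichment tools — computed via the
survival function and verified in the test suite against exact integer
pmf summation for all population sizes ≤ 60. The background population is
the analysed matrix's genes present in the annotation file, not a whole
genome, keeping the artifact self-contained. No multiple-testing
correction is applied by default because the comparison methodology sweeps
raw significance levels; a Bonferroni flag exists. GO-hierarchy
propagation is deliberately not performed: terms are used exactly as
annotated. The "restricted" comparison additionally requires at least half
of a bicluster's genes to carry any annotation before it may count as
enriched. Pattern recovery reports, per algorithm × term, the largest
per-bicluster count of genes annotated to the term, flooring isolated
single-gene hits to 0.

## Bayesian network learning

The family score is the standard BDe term with total pseudo-count `ess`
split uniformly over parent configurations × child states
(α_jk = ess/(q·r)); `ess = 1` with a uniform structure prior is the
neutral default. Scores are decomposable, so the hill climber caches
family scores and updates only changed families; a test asserts the
incremental totals equal full recomputation to 1e-9.

Search is steepest-ascent from the empty graph over single-edge additions,
deletions and reversals, with acyclicity checked by reachability and a
deterministic lexicographic tie-break on (move type, source, target) —
runs are exactly reproducible and, e.g., a perfectly copied pair of
variables learns the edge in gene-order direction. A move must improve the
score by more than 1e-9 to be accepted (guards float-noise loops).

*Limitations, measured:* greedy search does not always reach the global
optimum even at 3–4 nodes. Collider (v-structure) data with marginally
independent parents makes every first move on one side score negative;
small samples (≲ 50) create path-dependence traps; and large `ess`
(≥ ~100) densifies the optimum itself (the Dirichlet prior then favours
edges on pure noise — so "independent data ⇒ empty graph" holds at
moderate `ess`, not large). The oracle-equivalence suite therefore asserts
exact equality with exhaustive DAG enumeration on identifiable instances
(chains/forks/noise, 150–400 samples, ess ≤ 1) at a ≥ 33/36 match rate,
the hard bound greedy ≤ optimum everywhere, and exact equality on all
2-node instances, where the move space covers the whole DAG space.

The sparse-candidate variant restricts each node's parents to its `c`
highest empirical mutual-information partners (ties by gene order);
`c = 5` is the conventional setting when the mode is enabled.

Per-bicluster learning restricts the matrix to the bicluster's genes and
conditions, discretizes that submatrix, and learns one DAG per bicluster;
subnetworks merge by directed-edge union with duplicates removed. Edge
direction is retained through merging because the evaluation universe is
ordered pairs.

## Evaluation

The confusion matrix counts all N(N−1) ordered pairs of the declared gene
universe; undirected gold interactions are expanded to both orientations
before counting. Single-point areas: AUROC = (TPR + 1 − FPR)/2 (trapezoid
through (0,0), (FPR,TPR), (1,1)); AUPR is the trapezoid through (0,1),
(recall, precision), (1, prevalence), with precision defined as 1 at zero
predictions. Reported values are rounded half-away-from-zero to 4
decimals.

The indirect-edge reclassification treats the gold network as undirected
for path queries and uses paths of length exactly two (one intermediate
gene): an FP pair with a two-hop gold connection becomes TP, and an
untouched non-edge pair with such a connection becomes FN. Pair-universe
totals are conserved; on tiny universes the modified matrix can exhaust
one class, in which case the modified areas are undefined and reported as
absent. The statistical meaning of the TN→FN rule is inherited from the
evaluation methodology being reproduced, not endorsed.

Topology: mean degree 2E/N over the declared universe, density
2E/(N(N−1)), and diameter as the maximum eccentricity within the largest
connected component of the undirected view.

## Synthetic benchmarks

The expression generator overlays pattern blocks (constant shift; additive
row+column effects drawn uniform(−a, a); order-preserving staircases of
step *a* along a hidden column order) on Gaussian noise, with uniform
missingness; it returns the planted biclusters as ground truth. It does
**not** model dye bias, print-tip effects, intensity-dependent variance or
time-series autocorrelation, so passing recovery benchmarks demonstrates
algorithmic correctness on idealized coherent structure, not performance
on real microarray noise.

Block patterns are matched to algorithm families: additive rows spanning
all conditions for Cheng–Church (see its limitation above), a +4σ
constant module for ISA, an order-preserving staircase for OPSM, and
well-separated gene groups for k-means. The end-to-end benchmark plants
three additive modules in a 100 × 40 matrix (σ = 1, amplitude 4) — additive
rather than constant, because inside a constant block's own submatrix the
genes are conditionally independent and a structure learner correctly
finds nothing, whereas shared column effects give the learner real
dependencies. The gold standard is the union of complete DAGs over each
module's genes; the merged predicted network's AUROC is compared with a
degree-matched uniformly random network (median over 10 seeds). Problem
sizes (50-replicate skeleton recovery at 500 samples; 10-seed end-to-end
at 100 × 40) keep the full benchmark suite under a minute on one CPU while
leaving comfortable statistical margins.

The planted Bayesian network draws a random topological order, keeps each
forward edge with probability 0.5, samples conditional tables from
symmetric Dirichlet(1), and generates ancestral samples. Dirichlet tables
occasionally come out near-uniform, which is why 3-node skeleton recovery
plateaus near ~85% rather than 100% — the failures are statistically
unidentifiable instances, not search errors.

## Pipeline

Stages communicate through files (expression TSV, bicluster text format,
2-column edge lists / SIF, annotation TSV or GAF), so externally produced
bicluster results can replace any internal algorithm at the bicluster
stage. All stage outputs are written only after every stage has succeeded,
and a manifest records versions, seeds, parameters, shapes and edge
counts. With a fixed config and seed, reruns are byte-identical (the
manifest's wall-time field aside). Per-algorithm RNG seeds are derived
deterministically from the global seed, so adding an algorithm does not
perturb the others.
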