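# Methods

This note documents the models, estimators and numerical choices behind
`muscle-sc`, and what the synthetic benchmark does and does not show
about real tissue data.

## The analysis problem

A pre/post-exercise single-cell experiment yields gene×cell count
matrices for several subjects at two timepoints. The pipeline answers
three questions: (1) which cell types are present and in what
proportions, before and after exercise; (2) which genes each cell type
regulates in response to exercise; (3) whether the myogenic compartment
(satellite cells → maturing myocytes) shifts along its differentiation
continuum after exercise, and by how much.

## Pre-processing

Cells are kept when they detect between 200 and 3000 genes (inclusive)
and their mitochondrial count fraction is strictly below 15% (high
mitochondrial content marks lysing and apoptotic cells); mitochondrial
genes are recognized by the `MT-` symbol prefix (configurable). The
cell filter runs first; genes expressed in at most 20 of the remaining
cells are then removed — this order is a choice (the gene rule refers
to cell counts), and the removal report records it. Normalization is
global scaling: counts divided by the cell total, times 10⁴, then
natural log with a pseudo-count of 1. Zero stays exactly zero, so
sparsity is preserved.

Highly variable genes are ranked by dispersion (variance/mean of
normalized expression) standardized within 20 equal-frequency mean
bins; ties break alphabetically and flat genes always rank last. The
top-2000 submatrix is z-scored per gene (sd floored at 1e-8, values
clipped at ±10 to bound outlier leverage) and decomposed by exact PCA
(eigendecomposition of the feature covariance). Each component's sign
is fixed so its largest-magnitude loading is positive — downstream
trajectories are then reproducible run to run. Seven PCs are retained
by default; the elbow is not auto-selected.

The neighbour graph is batch-balanced: every cell takes its k = 3
nearest neighbours (Euclidean, PC space) *within each sample*, and the
union is symmetrized before community detection. This prevents a large
sample from monopolizing neighbourhoods without any model-based batch
correction.

## Clustering, doublets, annotation

Leiden community detection (resolution 1.0, fixed seed) partitions the
symmetrized graph. Leiden deliberately over-partitions large
homogeneous types — several clusters per type is the expected outcome,
and the consensus annotation merges them at the type level.

Doublets are scored per sample with the artificial-nearest-neighbour
scheme. Artificial doublets (25% of the real cell count) are mixtures
of random cell pairs built on the de-logged, library-normalized scale —
a physical doublet pools its parents' transcripts, so parents
contribute proportionally to their library sizes, and the mixture is
re-sampled at an empirical sequencing depth (Poisson) so artificial
doublets match the detection-rate distribution of real libraries.
Averaging log-scale profiles instead places artificial doublets off the
real-doublet manifold and breaks detection. Real and artificial cells
are co-embedded with the pipeline's own HVG/PCA settings; pANN(cell) is
the fraction of artificial doublets among its ⌈pK·n⌉ nearest
neighbours. The neighbourhood fraction pK is chosen on the grid
{0.005, …, 0.3} by maximizing the mean-variance-normalized bimodality
coefficient: BC = (skewness² + 1)/kurtosis of the pANN distribution is
computed for each (pN, pK) over a sweep of artificial-fraction subsets
pN ∈ {0.05, …, 0.25}, and BC_mvn(pK) is the mean over the sweep divided
by its variance. Two stabilizers matter in practice: the variance term
is floored (1e-3) because over a short nested sweep it is estimation
noise, and the pipeline applies the *median* of the per-sample pK
choices to all samples of an experiment — the single-sample BC
landscape is bimodal in pK (a platykurtic large-neighbourhood artifact
sometimes beats the true small-pK mode), and one misfired sample would
otherwise remove a biological subpopulation wholesale. The top
⌊0.075·n⌋ cells per sample by pANN are called doublets (ties at the
quantized small-k pANN break by the widest-neighbourhood pANN, then
index), and clusters whose called fraction exceeds 60% are removed
entirely, singlets included.

Known limitation: artificial-pair detection cannot see homotypic
doublets (~30% of pairs under the default composition), and the
generator deliberately rescales doublets to single-cell library sizes,
removing the depth cue; recall therefore plateaus near 0.45. Cells of a
differentiation continuum resemble mixtures of its extremes, so some
transitional cells are inevitably flagged; with the consensus-pK rule
this false-call rate stays at the base rate rather than concentrating
in one τ region.

Annotation runs three independent labellers per cluster: (1) marker
evidence — the type maximizing Σ(−log10 fdr) over the cluster's
significant markers shared with the reference set; (2) overlap — the
type with the smallest hypergeometric upper-tail p of the overlap
between cluster markers and reference set, with the universe equal to
all tested genes; (3) profile — the type whose reference mean profile
has the highest Spearman correlation with the cluster's mean profile
(skipped when no reference profiles are supplied, in which case methods
1 and 2 must agree). A method abstains when it has no positive
evidence: zero marker overlap, overlap p ≥ 0.05, or non-positive
correlation. Abstentions cannot form a consensus, so a cluster handed
an uninformative reference comes out `ambiguous` rather than
confidently mislabelled. The consensus needs ≥ 2 agreeing votes.

## Statistics

All two-group comparisons are unpaired two-sample Wilcoxon rank-sum
tests. When the pooled sample has ≤ 20 observations and no ties the
null is enumerated exactly; otherwise mid-ranks with the tie-corrected
normal approximation and continuity correction are used. (The grouped
form used for marker and DE scans computes mid-ranks once per cell set
and derives each group's U statistic from its rank sum — algebraically
identical to the per-gene test, linear instead of quadratic in the
number of groups.) Markers require BH-fdr < 0.05, positive log2 fold
change (de-logged means with a 1e-9 pseudo-count — the fold-change
definition is ours, as none is standard) and detection in ≥ 50% of the
cluster's cells. Exercise DE within a cell type requires detection in
strictly > 50% of cells at *both* timepoints, tests post vs pre with
cells as replicates (pseudoreplication, mirroring the original design;
a per-subject aggregation mode exists but is off by default), and
adjusts within the cell type. Composition shifts are one-sided rank-sum
tests on per-sample proportions; at 3 vs 3 samples with complete
separation the exact tail is 1/C(6,3) = 0.05, and at 4 vs 4 it is
1/70 ≈ 0.0143. Over-representation uses the hypergeometric upper tail
against an explicit background with BH across sets. Bulk/single-cell
detection overlap calls a gene bulk-detected when logCPM > 4 (strict)
and single-cell-detected when some cell type expresses it in ≥ 50% of
cells with positive mean.

## Principal-curve pseudotime

The curve fitter is Hastie–Stuetzle projection–expectation: initialize
with the first-principal-component line; repeat {project every point
orthogonally onto the current polyline (every segment checked,
distance ties resolved to the smaller arc length); sort by the
arc-length coordinate λ; smooth each coordinate against λ with a
tricube local-linear smoother (span 0.6 of the points) hardened by two
lowess-style bisquare robustness iterations on the joint residual norm;
re-parameterize nodes by cumulative chord length} until the relative
change in total squared projection distance falls below 1e-4 or 50
iterations pass. If a smoothing step would increase the projection
loss, the previous curve is kept and iteration stops, so the loss path
is non-increasing by construction; an infinite tolerance returns the
plain PC1 projection after one iteration. Non-convergence is reported
honestly via `converged_`.

Pseudotime is the arc length of each cell's orthogonal projection.
Orientation anchors the PAX7-high quartile of myogenic cells at λ = 0.
The exercise shift per lineage is Δ% = 100·(mean λ_post − mean
λ_pre)/L, where L is the total curve length — the denominator is a
design decision, stated here because a percent shift is meaningless
without one. A two-sided rank-sum p on λ accompanies it (the one-sided
p in the direction of Δ is also reported), together with both ECDF
step tables. Mean (not median) is the central tendency, matching an
overall-shift/ECDF reading; gene trends along the curve are ordinary
least squares of normalized expression on the coordinate, reporting
slope, Pearson r, r², and the slope's two-sided p (r is signed; r² is
its square).

At desk scale the recovered Δ% underestimates the injected shift by
roughly 20–30%: noise extends the fitted curve beyond the signal
endpoints, inflating L. The effect shrinks with cell count and is a
property of the estimator, not a bug; tests therefore compare the mean
recovered shift over seeded replicates against the injection with a
±3-point band.

## The synthetic atlas

The generator emulates the study conditions: 4 subjects × 2 timepoints
× 1000 cells; six types at the observed compositions (endothelial
44→37%, mesenchymal 26→27%, myogenic 18→18%, pericyte 6→5%, lymphocyte
4→9%, monocyte 2→4%); counts negative-binomial with shared size 10
(UMI-scale technical noise is near-Poisson; biological variability is
explicit in the design); lognormal library-size factors (sdlog 0.2,
a post-QC-scale spread); Beta(3, 57) mitochondrial fractions with 2%
outlier cells above the QC cutoff; 7.5% doublets formed by summing two
same-sample parents and binomially thinning to an empirical library
size (deterministic rounding would delete the count-1 stratum).
Expression is compositional: each cell's mean vector is normalized to a
common expected depth, so differentiation and cell type change the
transcriptome's composition while sequencing depth remains a purely
technical factor.

Each type carries canonical markers (fold 4–8) plus a 30-gene program
at fold 3 — real cell types differ in broad programs, not in a handful
of genes. The myogenic compartment sits on a latent differentiation
time τ ~ Beta(1, 1): cells populate the whole trajectory, as the
observed progenitor/fast/slow subpopulations do. Trend genes have mean
multipliers exp(β·τ): canonical progenitor markers fall (PAX7 β = −2.5,
MYF5 −2.0, …), maturation markers rise (TNNI1/TNNC2 +2.0, …), plus a
100-gene program at β = ±2 expressed at troponin-like levels (fold 10)
— differentiation from satellite cell to myocyte is one of the largest
transcriptional transitions known, and the continuum must dominate
within-compartment variance for any trajectory method (including the
real analysis) to see it. Post-exercise, τ is shifted by +0.08, clipped
at 1. Ground truth records every per-cell type, doublet flag and τ.

What the generator does not model: ambient RNA, batch chemistry
effects, UMI saturation, cell-cycle structure, per-gene dispersion, or
correlated gene programs beyond the designed ones. Passing tests
therefore demonstrate correct recovery of the designed structure under
realistic count noise — not robustness to every artifact of real
tissue dissociation.

## Problem sizes used by the test suite

The default atlas is 8000 cells (≈ 1450 of them myogenic) — large
enough that the myogenic sub-PCA has a stable leading axis, small
enough for repeated end-to-end runs. Null-calibration replicates use
1200-cell atlases (2 subjects, 800 background genes), which preserve
every stage's behaviour at a fraction of the cost. The shift-recovery
check averages five seeded full-pipeline runs; single-replicate
sampling error of the shift estimate is ~1.5 percentage points at
~700 myogenic cells per timepoint.

## Determinism

Every stochastic step is seeded: the generator from the design seed,
Leiden and the doublet detector from the pipeline seed (per-sample
offsets for the latter). Artificial doublet pairs are drawn in a
content-based canonical cell order, so doublet scores are exactly
equivariant under permutations of the input cells. Two runs with the
same configuration and seed produce byte-identical TSV outputs.
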