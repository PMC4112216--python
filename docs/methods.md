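# Methods

## Scope and model

`wallnet` implements an unsigned weighted co-expression network analysis with
trait integration. The modelling assumptions are:

* Expression profiles are log-scale intensities; only their correlation
  structure matters, so every stage is invariant to per-gene affine
  transforms.
* Co-regulation is symmetric and sign-blind: similarity is the absolute
  Pearson correlation (S_ij = |cor(x_i, x_j)|), so a repressor and its
  targets land in one module. No signed-network variant is offered.
* Modules are branches of the average-linkage dendrogram of 1 − TOM that are
  large enough (≥ `min_module_size`, default 50) and internally coherent;
  each is summarised by one latent pattern, its eigengene.
* Traits are linear readouts of module activity plus noise; both the
  correlation screen and the regularized CCA assume approximately linear
  trait–eigengene relationships at small sample size (n ≈ 29 tissues).

## Network construction

**Soft threshold.** A_ij = S_ij^β off-diagonal with diagonal fixed at 1;
connectivity sums always exclude the diagonal, making k_i the standard node
strength and the TOM denominator well defined. β is selected by scanning
integer powers 1..20 and taking the smallest with signed scale-free fit
R² ≥ 0.8 (falling back, with a warning, to the maximiser when none passes).
The fit recipe is stated exactly because it determines the selected power:
connectivities are placed in 10 equal-width bins, empty bins are dropped, a
line is fitted to log10(bin frequency) against log10(bin mean connectivity),
and the score is −sign(slope)·R², so a decaying distribution scores
positively. Computation is single-block; a block-size parameter is accepted
for interface compatibility but ignored with a warning, since blocks exist
purely to bound memory at scales this package does not target.

**TOM.** TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij) with
l_ij = Σ_{u≠i,j} a_iu a_uj, computed as a single matrix product on the
zero-diagonal adjacency; the diagonal is set to 1 and values clipped to
[0, 1] against rounding. A triple-loop implementation of the same definition
is kept in the test suite as an oracle.

## Module detection

Tree cutting is a quantile-height cut rather than the dynamic branch-shape
heuristics used elsewhere: the dendrogram is cut at the `cut_quantile`
(default 0.9) quantile of its merge heights, and each resulting component of
sufficient size is recursively re-examined at the same quantile of its own
subtree heights. A component is split when this yields two large children, or
one large child occupying at most half of the branch (a coherent minority
inside a diffuse cluster — the remainder falls back to unassigned). The
recursion is what separates planted modules whose branches happen to join
below any single global threshold, a failure mode a purely static cut cannot
avoid at high soft-threshold powers where TOM dissimilarities saturate near 1.
A static single-cut mode (`recursive=False`) is retained.

Two quality passes follow, in this order:

1. **Coherence filter** (`coherence_min`, default 0.2): a detected branch is
   dissolved to label 0 when its eigengene explains less than 20 % of member
   variance. A branch of mutually uncorrelated genes can satisfy the size
   rule while its leading variance fraction stays near the random-matrix
   baseline (~1/min(genes, samples) ≈ 0.05 here); genuine modules under the
   default noise level score ≥ 0.5, so the threshold sits in a wide gap.
   Running the filter before merging matters: a diffuse cluster containing a
   small coherent fragment can otherwise capture a real module during
   eigengene merging.
2. **Merging** (`merge_cut_height`, default 0.20): the module pair with the
   smallest eigengene dissimilarity 1 − cor(ME_a, ME_b) is merged while below
   the cut, eigengenes recomputed after every single merge (deterministic,
   matching iterative tree-based merging), then labels renumbered 1..M by
   descending size.

An optional kME pass (`reassign_kme`, off by default) joins unassigned genes
to the module whose eigengene they track with correlation ≥ 0.3.

**Eigengenes.** Member genes are standardised (mean 0, sd 1 across samples,
sample sd); the eigengene is the first right-singular vector over samples,
unit Euclidean norm, variance explained = leading squared singular value
fraction. PCs are sign-ambiguous, so orientation is fixed: the mean
correlation with member genes must be non-negative, with an exactly balanced
module (mean 0) oriented positively toward its first member by ID. A
deterministic rule here is required for byte-identical reruns.

## Trait linkage

P-values are two-sided Student asymptotic throughout
(t = r√(n−2)/√(1−r²), df = n−2, p = 0 at |r| = 1); the study this emulates
reports positive correlations but never states sidedness, and two-sided is
the conservative default. No multiple-testing correction is applied anywhere
in the correlation stage, matching the upstream practice; enrichment offers
an optional Benjamini–Hochberg column.

The candidate screen reads "p lower than 75 % of all p-values" as "strictly
below the 25th percentile (linear interpolation) of the p-value population".
The population is per module and per trait by default — the usage the
method was designed for — with a pooled mode available. Strict inequality
makes the all-equal-p case select nothing rather than everything. The rule
by construction selects at most ~a quarter of the genes. Subgroup labels
use a canonical abbreviation table (cellulose→Cel, xylose→Xyl, ...); exactly
two traits give "A + B" in canonical order, three or more give "Multi".

## Regularized CCA

With 29 samples and potentially ≥ 29 eigengenes, classical CCA is degenerate
(every canonical correlation is 1), so the within-block covariances are
ridge-penalised: (Σ_XX + λ_X I, Σ_YY + λ_Y I), default λ = 0.1 for both
blocks; the λ = 0 path raises an explicit error on rank-deficient blocks
instructing regularization. Columns are standardised first. The solver
whitens both blocks (inverse square root via eigendecomposition) and takes
the SVD of the whitened cross-covariance; this reduces to |cor| in one
dimension and reproduces the textbook generalized-eigenproblem solution to
1e-8, which the tests check through an independently coded eigen-solver.

Structure correlations correlate the original columns with the first three
canonical variates (component count and the variate convention are
config-exposed: X-block, Y-block, or their average (U+V)/2, the default
used for relevance networks). Similarity scores are the cross-block inner
products of structure correlations, clipped to [−1, 1]; edges require
|score| ≥ τ = 0.5. An isolated trait triggers a warning by default; rescue
mode (opt-in) adds its single strongest edge, flagged as rescued, since
non-isolation was an observed property of the original network, not an
enforced one.

## Enrichment

Classic per-term one-sided tests only: hypergeometric upper tail
P(X ≥ k) and one-sided Fisher's exact on the equivalent 2×2 table, asserted
numerically identical in the tests. The graph-based "weighted" decorrelation
across GO terms is deliberately not reproduced — it is a large external
heuristic incidental to this package's purpose — and reports are labelled
"classic". The universe defaults to all genes in the post-preprocessing
matrix.

## Preprocessing

"Below the negative-control background" is read as: per sample, threshold at
the 0.8 quantile (linear interpolation) of the control intensities; a probe
is removed when it falls below threshold in *any* sample (default) or in
*all* samples — the literal any-tissue rule discards tissue-specific genes,
so both are exposed and neither is asserted as the original choice. Probe
collapse keeps, per gene, the probe with the highest mean intensity
(ties: lexicographically smallest probe ID); per-gene averaging is offered
as an alternative. Zero-variance rows are dropped with a warning because
correlation is undefined on them.

## Synthetic data

The generator emulates a multi-tissue expression panel: 29 samples; five
planted modules of 100 genes, each gene w_i·e_m + ε with loadings w_i uniform
on (0.6, 0.95), latent profiles e_m i.i.d. standard normal over samples then
centred, residual sd 0.5; 200 pure-noise genes. These defaults give
within-module correlations around w²/(w²+σ²) ≈ 0.6–0.7 against a null of
|r| ≈ 0.15 at n = 29 — strong but not trivial planted structure at desk
scale. Traits are c_t·e_m + η (c = 1, η sd 0.3) mapped affinely onto the
published compositional ranges (cellulose 0.29–31.33 % dry matter,
Xyl 3.49–245.82, Ara 3.26–41.07, Gal 0.03–14.81 mg/g, H 4.93–71.72,
G 1.18–107.19, S 1.06–25.42 μmol/g); cellulose, Xyl and the monolignols
share one driving module and Ara/Gal a second, mirroring the coordinated
lignocellulose and arabinoxylan-substitution axes seen in real composition
data. Units are free-text metadata, carried through but never parsed.

What the generator does **not** emulate: array-level artefacts (no CEL-level
simulation, normalisation effects or batch structure), overlapping module
membership, nonlinear trait responses, heteroskedastic or heavy-tailed
noise, and the tens-of-thousands-of-genes scale of a real chip. Passing
tests therefore demonstrate correctness of the algorithms under clean
planted structure, not robustness to every pathology of real microarray
data. Probe-level simulation adds 1–3 probes per gene (constant
probe offset sd 0.25, per-sample noise sd 0.1) and flat negative controls
centred 3 global-sd below the gene mean.

## Numerical choices and degenerate inputs

* Symmetry is enforced to 1e-10 and re-symmetrised after arithmetic; TOM,
  similarity and dissimilarity are clipped to [0, 1].
* Correlations within 1e-12 of ±1 are snapped so declared limits (p = 0)
  hold exactly; the connectivity table computes kWithin and kOut as separate
  sums so kTotal = kWithin + kOut is exact in floating point.
* All-equal connectivities, all-constant modules, empty control sets, empty
  modules and rank-deficient unregularized CCA raise (or warn and return the
  declared degenerate value) rather than producing NaN.
* Every random draw flows from an explicit integer seed; reruns of the
  pipeline with one seed produce byte-identical summaries.

## Problem sizes

The test suite and the acceptance script run the full study at 700 genes ×
29 samples (five seeds), oracle comparisons at 20-gene instances, and
screening at 120-gene instances — sizes chosen so the complete evidence
chain executes in seconds on one CPU while keeping the planted-structure
recovery non-trivial.

## Known limitations

* The tree cut is a quantile-height heuristic, not a reimplementation of the
  published dynamic hybrid algorithm; on real data the two can split borderline
  branches differently. The divergence is recorded in the run config.
* The module meta-network edge rule (|cor(ME_a, ME_b)| ≥ 0.5) is a documented
  stand-in; the original figure it emulates does not specify its construction.
* Ridge penalties, the retained component count (3) and the variate
  convention for structure correlations are package defaults, not values
  recovered from the emulated study, which does not print them.
* No sparse/approximate TOM, no consensus (multi-dataset) modules, no sparse
  CCA, and no permutation p-values for canonical correlations.
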