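# Methods

This note documents the models and procedures implemented in
`coexdiff`, the parameters that matter, the numerical choices made where
the design was genuinely open, and what the synthetic benchmark does and
does not establish.

## Signed co-expression networks

Co-expression similarity is the Pearson correlation of per-gene
expression profiles across the samples of one condition (≥ 3 samples,
positive per-gene variance required; the matrix is symmetrized by
averaging with its transpose and clipped to [−1, 1]). The signed
adjacency

    a_ij = ((1 + cor(i, j)) / 2) ** beta

maps anti-correlated pairs toward 0 rather than conflating them with
positive co-expression. The soft-threshold power `beta` is selected by
the scale-free topology criterion: connectivities k_i = Σ_{j≠i} a_ij are
binned into 10 equal-width bins, log10 frequency is regressed on log10
mean bin connectivity over occupied bins, and the smallest integer power
(candidates 1–20) with R² > 0.8 *and negative slope* is taken. The
negative-slope requirement stops the criterion from accepting
anti-scale-free fits. If no candidate qualifies, the power maximizing R²
is used, a warning is logged, and the scan carries `criterion_met =
False`; downstream behaviour is unchanged. Both condition networks share
the power selected on the reference condition by default (override
available) — re-selecting per condition would confound preservation
statistics with threshold differences.

The topological overlap matrix uses the standard formula

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),  L_ij = Σ_u a_iu a_uj

applied to the signed adjacency (which is nonnegative, so the formula is
well defined); TOM is clipped to [0, 1], its diagonal fixed at 1, and
1 − TOM (zero diagonal) is the clustering dissimilarity. Matrices are
dense `float64`; the intended scale is ≤ ~20,000 genes with a small
constant number of n×n arrays alive at once.

## Module detection

1 − TOM is clustered with average linkage (UPGMA, via
`scipy.cluster.hierarchy`). Branches of the dendrogram become modules
through a hybrid dynamic cut with parameters deep_split ∈ {0..3},
cut height (default 0.99), minimum module size (default 27) and an
optional PAM-like stage (default on).

The branch criteria are scale-free by design. For a branch attaching to
the rest of the tree at height `attach`, with its own top merge at `top`
and mean internal merge height (core scatter) `scatter`, the *relative
separation*

    r = (attach − top) / (attach − scatter)  ∈ [0, 1]

is the fraction of the branch's height footprint accounted for by clear
separation from its surroundings. A genuine cluster hangs well below its
attachment relative to its own internal spread (r large); an arbitrary
bipartition of a homogeneous cluster has merges reaching almost to the
attachment (r ≈ 0). A join is split into two modules when both children
have size ≥ min_size and r ≥ τ(deep_split), with τ = 1 − {0.64, 0.73,
0.82, 0.91} — the conventional core-scatter ladder — so higher
deep_split splits more aggressively. Labelling a whole branch as one
module always requires r ≥ 0.36 (the most conservative level): since
deep_split then only adds splits, the number of detected modules is
nondecreasing in deep_split, and loosely attached noise-padded blobs
never qualify wholesale. Joins that neither split nor qualify are
transparent — the walk descends with the ambient attachment height
unchanged, so chained outliers are stripped while tight sub-branches
surface.

This self-normalizing formulation was chosen over thresholds expressed
as absolute fractions of the h_min–cut_height range because
topological-overlap dendrograms of weakly co-expressed modules compress
the informative structure into a thin height sliver just under the cut
height; absolute thresholds there either grey out real modules or let
mixed blobs qualify as one.

The PAM stage assigns each unlabelled gene to the nearest module (by
average dissimilarity to its members) when that distance is within the
module's radius (the largest average member-to-co-member dissimilarity).
Modules are renamed by decreasing size along the conventional color
sequence (turquoise, blue, brown, …), grey holding the unassigned genes.

Module eigengenes are the first right singular vector over samples of
the per-gene standardized (population denominator) module submatrix,
sign-aligned so the eigengene correlates nonnegatively with the mean
standardized module profile; variance explained is the top squared
singular value fraction. kME is the correlation of a gene with a module
eigengene. Optional eigengene merging joins the closest module pair
while their normalized eigengene dissimilarity (1 − cor)/2 is at or
below the threshold, recomputing eigengenes after every merge; the
(1 − cor)/2 scaling keeps the threshold on [0, 1] with 1 collapsing
everything and 0 disabling merging. Merging is off in the default
pipeline.

## Module preservation

For each reference module, six statistics are computed in/between the
networks: density in the test condition (mean within-module adjacency,
mean within-module correlation, eigengene variance explained) and
cross-condition connectivity agreement (correlation of intramodular
connectivity vectors, of vectorized within-module adjacencies, and of
within-module correlations). The null re-evaluates all six on random
gene sets of the same size drawn from the shared gene universe
(module-label permutation; 200 draws by default, seeded). Each statistic
yields Z = (observed − mean_null)/sd_null; Z_density and Z_connectivity
are the medians of their families and

    Z_summary = (Z_density + Z_connectivity) / 2.

Calibration thresholds: ≤ 2 no evidence, 2–10 weak-to-moderate, > 10
strong (boundary values fall to the lower category). Disease-module
selection takes modules with Z_summary below a cutoff (default 5),
ascending, excluding the artificial grey (unassigned) and gold (random
sample of min(1000, n/5) genes, added for calibration) modules.

Degenerate nulls: when a null is constant to floating-point precision
(sd ≤ 1e−12), the Z is a ±inf sentinel if the observed value differs
from it and NaN (undefined) if it coincides — the latter occurs for all
cross-network connectivity correlations when test and reference networks
are identical, where every gene set scores exactly 1. NaN statistics are
excluded from their family median; a family with no defined member drops
out of the summary mean. All degenerate cases are flagged, never
silently dropped.

A practical caveat established on the synthetic benchmark: with a
structured gene universe, random gene sets inherit preserved block
structure, so the connectivity Z of a genuine but weakly co-expressed
module (mean loading ≲ 0.65 at 40 + 40 samples) is near zero or mildly
negative while its density Z is large. Such modules land at Z_summary ≈
2–10 — weak-to-moderate — rather than > 10. This mirrors real studies,
where uncontested modules frequently sit in the 5–10 band, and means the
strong/weak boundary should not be read as intact/destroyed: destroyed
modules fall clearly below 0, intact weak ones hover in the weak band.

## SAM-style pre-filter

Two-class unpaired SAM: d_i = (mean difference)/(s_i + s0) with s_i the
pooled standard error of the mean difference. The fudge factor s0 is the
percentile of the s_i distribution (0, 5, …, 100) minimizing the
coefficient of variation of the windowed median absolute deviation of d
across 20 s-quantile windows; a fixed s0 can be supplied. Selection
compares sorted observed d with the mean of sorted permuted d over 100
label permutations (seeded): gene at rank i is selected when
|d_(i) − d̄_(i)| > delta, which makes selections nested (monotone) in
delta. Genes missing in > 20% of either group's samples are dropped with
a logged warning; means and scatters are computed over available values.

## Topology and enrichment

Selected modules are exported per condition as undirected, unweighted
graphs: edge (i, j) iff TOM_ij ≥ threshold (adjacency selectable).
Because any absolute export threshold is arbitrary, the default policy
picks, per module and condition, the smallest threshold keeping edge
density ≤ 0.15, and records it in the run metadata — the threshold is
the least reproducible choice in this kind of workflow and is logged
prominently for that reason. Betweenness is unnormalized, fractional
(σ_st(v)/σ_st), each unordered pair counted once, disconnected pairs
contributing zero (computed with networkx's dependency-accumulation
implementation and verified in the tests against exhaustive shortest-path
enumeration). The differential table takes the union of both conditions'
module graphs, scores absent genes 0 with an absence flag, ranks by
descending betweenness (ties by gene id), and sorts by |ΔBC| with
Δrank = rank_ref − rank_test.

Enrichment is a one-sided hypergeometric upper tail on the overlap
between module and gene set, both intersected with the background
universe first, with BH correction within each module's batch of sets.
The default background is the post-filter analysis gene set — modules
are drawn from it, so a genome-wide background would overstate
significance. Reported hits require overlap ≥ 2 and q < 0.05.

## Synthetic data

Module m is driven by a per-sample standard normal latent factor e_m;
gene g in m expresses l_g·e_m + √(1 − l_g²)·ε with ε standard normal, so
marginal variances are 1 and the expected correlation of two members is
l_i·l_j. Loadings are jittered uniformly ±0.05 around the module mean.
Background genes are pure noise. In the test condition, preserved
modules redraw their factor (different samples, same wiring — precisely
what preservation statistics measure), destroyed modules give every gene
an independent factor, and differentially expressed genes (planted among
background genes, keeping the DE signal orthogonal to module structure)
gain a mean shift in within-group SD units. Everything derives from one
seed and is bit-reproducible.

The default scenario has 1,000 genes: 8 modules of sizes 75–100 (700
genes) with mean loadings 0.85 down to 0.60, 300 background genes of
which 50 carry a 3-SD shift, and 40 + 40 samples. The two destroyed
modules are strongly loaded ones (0.82, 0.80): a destroyed module must
be reliably detectable in the reference network before its loss of
preservation can be measured, so the perturbation is planted where
detection is unambiguous. The generator emulates log-scale,
post-normalization expression with Gaussian noise and exact factor
structure; it does not emulate probe-level artefacts, presence-call
patterns beyond all-present, batch effects, heavy-tailed noise or
correlated backgrounds — so passing tests demonstrate correctness of the
algorithms under the stated model, not robustness to those real-data
phenomena.

## Pipeline defaults and problem sizes

The orchestrated run uses: presence fraction 0.5, SAM delta 0.296 (100
permutations), candidate powers 1–20 with R² cut 0.8 and shared beta,
deepSplit 1, cut height 0.99, minimum module size 27, PAM on, merging
off, 200 preservation permutations with selection cutoff 5, TOM graph
export at density ≤ 0.15, enrichment overlap ≥ 2 and q < 0.05. The
reference condition defaults to the lexicographically first label and
should normally be set explicitly. On the synthetic scenario the SAM
stage is skipped (`skip_sam`): its differential shifts live in
background genes by design, so a tight SAM selection would strip the
module structure the later stages are exercised on.

Tests and the acceptance script run the full scenario at 1,000 genes
with 10–20 replicate datasets for rate estimates, 50–150 replicates for
null-calibration checks, and brute-force oracles at n ≤ 12; these sizes
keep every kernel verified while the complete suite stays in the
few-minute range on one CPU.

## Known limitations

* The hybrid cut is this package's own formulation of dynamic branch
  cutting; it reproduces the planted-module benchmark near-perfectly but
  is not output-identical to any external implementation, and exact
  module counts on real data will differ between hybrid-cut variants.
* Absolute betweenness values depend on the (inherently arbitrary)
  module-graph export threshold; only comparisons made under one
  recorded policy are meaningful.
* Preservation Z magnitudes depend on permutation count and universe
  structure; categories and rankings are stable, digits are not.
* Dense matrices cap practical problem size around 20k genes; no
  block-wise decomposition is provided.
* Unsigned/hybrid adjacency variants, biweight midcorrelation, consensus
  modules across > 2 networks, and network-distance enrichment scores
  are out of scope.
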