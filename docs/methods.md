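# Methods

## The problem

A single-cell dataset rarely comes with one authoritative clustering. Different
algorithms, resolutions, modalities (RNA, ADT, ATAC) and reference projections
produce conflicting cell-to-cluster assignments, each of which may be right
about some populations and wrong about others. `sctri` integrates these at the
*decision* level: instead of building a joint embedding, it scores every
cluster of every annotation set with stability metrics, treats each annotation
set as a player in a coalitional game, and assigns every cell to the annotation
with the highest Shapley importance for that cell. Unstable winners are then
pruned and their cells reassigned.

## Stability metrics

Let X ∈ R^(I×F) be the normalized cells × features matrix and let an
annotation set partition the I cells into clusters. Three views of cluster
coherence are scored per cluster c:

**Reassign score.** For each cluster, features are ranked by a Welch two-sided
t-test p-value (cluster vs rest) and by log-fold-change; the combined rank is
the mean of the two (best = 0) and the top 30 features per cluster form, by
union, a discriminative feature set L. A PCA with P = min(30, |L|−1, I−1)
components is fit on the L-restricted matrix (mean-centered, no rescaling) and
each cluster's centroid is the mean of its members in that space. The score is
the fraction of the cluster's cells whose Euclidean-nearest centroid is their
own: 1.0 in the separable limit, ≈ 1/k for arbitrary k-way splits of a
homogeneous population.

**TF-IDF(n) exclusivity.** Expression is binarized at value > 0. For feature f
and cluster c, TF = in-cluster detection fraction + ε and
IDF = −ln(global detection fraction + ε), with ε = 1e−5 guarding log(0);
exclusivity = TF·IDF. The cluster's score is the exclusivity of its nth-ranked
feature (n = 10 by default). A cluster with at least n private markers scores
high; arbitrary splits of a population inherit the parent's exclusivity (both
halves express the same genes), so this metric penalizes *under*-clustering —
a merged cluster's markers are diluted to TF ≈ 0.5 — while the reassign and
SCCAF scores penalize *over*-clustering. The optional n = 5 variant
(`tfidf_orders=(10, 5)`) promotes populations with very few exclusive markers.

**SCCAF score.** A multinomial L2-regularized logistic regression on all
features, evaluated by stratified 5-fold cross-validation; out-of-fold
predictions build a confusion matrix Ψ and a cluster scores its recall
Ψ_cc / Σ_k Ψ_ck. The printed alternative Ψ_cc / trace(Ψ) is available as
`sccaf_variant="trace"` but makes scores depend on the cluster count, so
per-cluster recall is the default. In-sample confusion would saturate at 1,
hence cross-validation. Cells are put in canonical (cell-id) order before fold
assignment so scores are invariant to storage order. Folds shrink to the
smallest usable cluster size (≥ 2); singleton clusters score 0.

## The coalition game

For one cell, D ∈ R^(A×M) holds its clusters' scores across A annotation sets
and M metrics. The marginal value of player a joining coalition T is computed
per metric: members of T ∪ {a} are ranked ascending with ties sharing the
maximal rank, the focal player's score is lifted by the offset (0.01) before
ranking, and — under the default `all_or_none` adjustment — the coalition size
|T ∪ {a}| is credited only when the focal player attains the top rank. The
`classic` adjustment credits the player's rank for every metric instead. The
Shapley value is the exact, factorial-weighted sum of these surpluses over all
2^(A−1) coalitions per player.

The offset treats score differences below 0.01 (on metrics that live on a 0–2
scale) as noise: near-equal players both top-rank and tie. It is applied to
the focal player only, which makes "tie" a slightly asymmetric notion but
matches the value-function definition exactly; a lone player always tops its
singleton coalition, so the minimum attainable Shapley value is M/A rather
than 0.

Cells sharing the same label vector across all annotation sets have identical
D, so importances are computed once per unique label combination — typically
a few dozen combinations for thousands of cells.

Each cell goes to the argmax-Φ annotation; exact ties go to the annotation
whose originating cluster is smallest (the more specific population), then
lexicographically by annotation name for determinism. Beyond 15 annotation
sets the engine switches to the full-coalition rank importance (no
enumeration); both the threshold and the method are configurable. An Elo-like
per-cluster quality — mean winner Φ normalized by the player count and the
cluster count — is reported for cross-run comparison.

## Pruning

A raw winner cluster keeps the "annotation@label" identity of its source. Its
winning fraction wf is the number of cells it finally won divided by the size
of its originating cluster. Clusters with wf < 0.25 or fewer than 10 cells
(both configurable) are unstable: clusters that win a sliver of their source
probably won by chance, and very small clusters have unreliable stability
estimates. Cells of unstable clusters are reassigned to the Euclidean-nearest
stable-cluster centroid in a marker-PCA space recomputed from the stable
clusters only. Pruning runs once, not to a fixpoint; wf is reported as
computed before reclassification.

## Modality contribution

For each final cluster the top-20 markers (combined rank as above) are
weighted by list position, 21−k for position k (top-1 = 20), and weights are
summed per modality tag. With ≥ 20 features the contributions always
partition 210, making clusters directly comparable.

## Agreement metrics

Homogeneity 1 − H(C|K)/H(C), completeness 1 − H(K|C)/H(K) and their harmonic
mean (V-measure) are computed from the class × cluster contingency table with
natural-log entropies; zero-entropy labelings return 1 by convention. Note
that completeness is *not* monotone under arbitrary coarsening of the
prediction (merging clusters that mix classes differently can lower it); the
guaranteed monotonicity is homogeneity under refinement.

## Synthetic data

The simulator follows the Splat generative structure: gene base means
Gamma(shape 0.6, rate 0.3); each gene is differentially expressed in group g
with probability `de_prob[g]`, with multiplicative factors
LogNormal(0.1, 0.4) inverted (1/f) with probability 0.5; library sizes
LogNormal(11, 0.2); a cell's expected counts are its library size times its
group's normalized mean profile; counts are Gamma-Poisson with biological CV
`bcv_common + 1/sqrt(mean)` (bcv_common = 0.1), inflated per gene by an
inverse-chi-square draw at 60 degrees of freedom. The mean-trended CV matters:
with near-Poisson noise, weakly expressed markers are implausibly easy to
detect and the distinction between the two TF-IDF orders disappears.

Two benchmark scenarios are built in. `experiment1`: 3000 cells, five groups
with proportions (0.23, 0.15, 0.15, 0.23, 0.24) and DE fractions
(0.15, 0.15, 0.15, 0.2, 0.4), plus four conflicting annotation sets — Broad
(c1+c2+c3 merged), Median (c2+c3 merged), Fine (c5 randomly halved) and
Excessive (c2 and c3 each halved) — none of which matches the truth.
`experiment2`: 3000 cells, six groups with proportions
(0.2, 0.2, 0.15, 0.15, 0.15, 0.15) and DE fractions
(0.2, 0.2, 0.005, 0.005, 0.005, 0.005), so c3–c6 differ in only ~0.5% of
genes; annotations are Broad (c3..c6 merged), Median (c3+c4 and c5+c6 merged)
and Fine (= truth). Splits are random 50/50 halves. The generator does not
model batch effects, outlier genes, explicit dropout beyond the Gamma-Poisson
noise, trajectories, or non-RNA modalities — so passing these benchmarks
shows the decision engine recovers planted partitions under realistic count
noise, not that it handles batch-confounded real data.

## Problem sizes and numerical choices

The benchmarks run at 3000 cells. Experiment 1 uses 2000 genes — the planted
structure there (≥ 15% DE per group) is recovered exactly at this size, with
five final clusters in 1:1 majority correspondence with the truth and
V-measure 1.0 across seeds. Experiment 2 uses the full 10,000-gene complement:
its subtle groups carry ~50 weak DE genes each, and it is precisely the
number of detectable exclusive markers that separates the TFIDF10-only run
(subtle pairs merge) from the TFIDF10+TFIDF5 run (all six groups recovered).
At 2000 genes the subtle groups hold ~10 DE genes and their recovery becomes
a coin flip — informative about the metric design, but not a stable
benchmark.

Other numerics: natural log everywhere; CLR uses a +1 pseudocount per cell
across features; marker t-tests use Welch (unequal variances) on normalized
values with NaN p-values treated as 1; rank ties use the "min" convention and
marker lists are tie-broken by feature id; nearest-centroid ties resolve to
the first cluster in sorted label order; winner ties use a 1e-9 tolerance on
Φ. Logistic regression runs at most 200 lbfgs iterations — scores are recall
ratios and are insensitive to the last decimals of the fit.

## Known limitations

Exact Shapley is exponential in the number of annotation sets (hence the
rank fallback above 15). Stability scores assume the concatenated feature
matrix is meaningfully normalized per modality; no batch correction is
attempted. The simulator is a structural re-implementation of the Splat
model, not a bit-compatible port. Tie-breaking by "smaller originating
cluster" favors specific populations by design and can be changed only by
editing the assignment step.
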