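# Methods

This note documents the statistical machinery behind `coexnet`: the model
each stage assumes, the parameters that matter, the synthetic data used to
exercise it, and the numerical and design choices made where the
literature leaves room.

## Co-expression model

The analysis assumes that transcriptional co-regulation induces blocks of
correlated genes ("modules") whose shared variation can be summarized by a
single latent component per module, and that clinical state may couple to
those components rather than to single genes. All stages operate on a
normalized log-scale genes × samples matrix; no count model is involved.

**Sample QC.** Outlying samples are detected on the sample network:
Euclidean distances between per-gene standardized sample profiles are
mapped to adjacency `A_ij = 1 − d_ij/max(d)`, connectivity is the row sum
over other samples, and its z-score `Z_k` flags outliers below −5. The
−5 default is deliberately permissive: it removes only samples whose
global profile is grossly disconnected, not biological extremes. A
correlation-based distance (`1 − r` between sample profiles) is available
via `distance="correlation"`. When every sample is equidistant
(`sd(k) = 0`) all `Z_k` are defined as 0 and nothing is removed.

**Soft thresholding.** Correlations are raised to a power β (default 6,
unsigned `|r|^β`) so the adjacency approximates a scale-free topology
while preserving continuous edge weights. `scale_free_fit` reports the
model-fit R² of log-frequency vs. log-connectivity (equal-width
connectivity bins; R² is negated when the slope is positive, so only a
decreasing degree distribution counts as scale-free) together with mean
connectivity per candidate power. β is dimensionless; larger values
sharpen module separation at the cost of sparser networks.

**Topological overlap and clustering.** TOM rewards gene pairs that share
neighbors, denoising the raw adjacency. `1 − TOM` is clustered by
average linkage (UPGMA, `scipy.cluster.hierarchy.linkage`, deterministic
given its input).

**Dynamic cut.** Fixed-height dendrogram cuts cannot serve modules of
heterogeneous tightness, so branches are accepted adaptively. A branch is
a module when (i) it has at least `min_module_size` (default 30) leaves,
(ii) its core — the leaves of the lowest subtree node reaching core size
— has mean pairwise dissimilarity below a threshold, and (iii) the gap
between the branch's joining height and that core scatter exceeds a
minimum. Both thresholds are expressed relative to the span between the
5th percentile of merge heights and the cut height (99% of the height
range), and are driven by `deep_split` ∈ 0..4 through the relative core
scatter limits (0.64, 0.73, 0.82, 0.91, 0.95) with minimum gap
`(1 − scatter)·3/4`; deeper splits give more, smaller modules. The
recursion splits a node only when both children qualify as distinct
clusters; otherwise the node is accepted whole if it qualifies, which
prevents modules from being shaved down to their cores. Unassigned
leaves go to "grey"; a PAM-like pass then attaches a grey gene to the
closest module if its average dissimilarity to that module is below the
module's joining height. This is an original implementation in the
dynamic-hybrid style; it is validated by planted-truth recovery (ARI
≈ 0.9–0.97 on the test fixtures), not by equivalence to any particular
reference implementation.

**Eigengenes and merging.** A module eigengene is the first right
singular vector (over samples) of the standardized module submatrix,
restandardized and signed so its mean correlation with member genes is
nonnegative. Modules whose eigengene dissimilarity `1 − cor` falls below
`merge_cut_height` (default 0.25) are merged iteratively to a fixed
point; the merged module keeps the largest member's label.
`reassign_threshold = 0` (default) disables post-hoc migration of genes
between modules. Color labels follow the canonical sequence (turquoise,
blue, brown, …) in decreasing size order, ties broken by smallest member
gene id; "grey" is reserved for unassigned genes.

## Association model

Module–trait association uses Pearson partial correlation: eigengene and
trait are each residualized (least squares, with intercept) on the
covariates — sex, age (years), age at onset (years), ethnicity code, and
cell-type fractions — and the residuals are correlated. The p-value uses
`t = r·sqrt(df/(1−r²))` with `df = n − 2 − q`. The same covariate set is
applied uniformly to ME–trait, GS, and GS–MM computations (a single
`adjusted` switch turns it off), since the ambiguity of attaching the
adjustment to one stage only has no principled resolution. Missing trait
values are handled pairwise-complete per cell with the n used reported;
samples with missing covariates are dropped (logged).

Multiplicity over the full module × trait family is controlled by
Benjamini–Hochberg at FDR α = 0.05 (statsmodels implementation). The
table also reports the data-dependent raw-p cutoff implied by the BH
decision — cohort analyses often quote such a cutoff (e.g., "p < 0.007")
which is a function of the observed p-values, not a constant of the
method, and is therefore never hard-coded. Percentile bootstrap intervals
(default B = 1000, samples resampled with replacement, seeded) accompany
each correlation; degenerate resamples are redrawn and counted, and more
than 50% degenerate draws is an error. BCa was not used: at n ≈ 90 and
moderate |r| the percentile interval's coverage (measured ≈ 0.93 for
r = 0.5) is adequate and the method is simpler to audit.

Hub genes require `|MM| > 0.8` and `GS > 0.3`, both dimensionless
correlations; MM is thresholded in absolute value because hubness is a
magnitude property. The trait of interest per module defaults to the
trait with the largest |r| for that module. Significant modules are
clustered on their trait-correlation vectors (Euclidean distance, average
linkage, default k = 2 flat clusters) and hub sets are pooled per
cluster.

A caveat the synthetic experiments expose: the GS–MM correlation within a
module is inflated whenever the module factor's *sample* correlation with
the trait is non-zero, even by chance (GS ≈ λ_g·|r̂| + noise tracks
MM ≈ λ_g). A significant GS–MM test therefore supports, but does not by
itself establish, a module–trait relationship; the ME–trait test is the
primary inference.

## Validation

**Stability.** 50 iterations (default) rerun the entire network +
module-detection chain on 80% of samples drawn without replacement
(fraction and scheme are config; the seeded generator makes runs
reproducible). Resampled modules are identified with reference modules by
maximal Jaccard overlap (ties toward the larger reference module); a
gene's consistency is the percentage of iterations in which it returned
to its reference module, and a module's stability is the mean over its
members. An iteration producing no modules counts as all-mismatch.

**External overlap.** Each (our module × external module) pair is tested
by the upper-tail hypergeometric law `P(X ≥ k)` on the universe of genes
present in both partitions (grey excluded on both sides), corrected by
Bonferroni over all tested pairs (BH available). The intersection
universe is the conservative choice when two studies assay different
platforms. Over-representation of hub sets against GMT gene sets uses
the same test per term (terms under 3 universe genes skipped) with BH
correction; a doubled-tail two-sided variant is exposed by flag.

## Synthetic studies

The generator plants exactly the structure the analysis assumes: per
module a latent factor `e_m ~ N(0,1)` across samples; member genes
`x_g = λ_g e_m + sqrt(1−λ_g²) ε_g` so `cor(x_g, e_m) = λ_g` and two
members correlate at `λ_i λ_j`; background genes are pure noise; a
coupled trait is `γ e_m + sqrt(1−γ²) noise` (plus optional covariate
effects), so the ME–trait correlation targets γ. Defaults emulate the
cohort shape of a ~90-sample clinical study: 15 modules of 200 down to 30
genes, 30% background, ten traits of which four couple to distinct
modules at |γ| between 0.35 and 0.5, sex ≈ 65% one class, age 25 ± 6
years, three ethnicity categories, Dirichlet(5) cell fractions over five
leukocyte types. Acceptance-scale experiments use a 1,000-gene slice
(six modules of 150–40 genes) so the full chain, including 50 stability
iterations, runs in seconds; gene count affects the multiple-testing
burden and runtime but not the per-module statistics under this model.

What the generator does *not* emulate — and what passing tests therefore
do not establish — includes probe-level microarray noise, batch effects,
count-based RNA-seq mean–variance structure, correlated module factors,
nonlinear trait couplings, and outlier samples unless planted. Cell-type
mixing signal is off by default so network recovery is not confounded;
deconvolution tests switch it on explicitly through their own mixtures.

## Numerical choices

- Correlations are clipped to [−1, 1]; TOM to [0, 1] and symmetrized
  after the matrix products; the TOM denominator is provably positive.
- Constant gene rows are an error wherever a correlation is required
  (they have no defined correlation), with offending genes named.
- Residual variance below `1e-8·max|x|·sqrt(n)` counts as zero (an exact
  linear dependence leaves only rounding noise).
- Eigengenes use one SVD of the standardized submatrix; a 1-gene module
  degenerates to that gene standardized (warned).
- BH adjustment, hypergeometric tails, NNLS and ARI delegate to
  statsmodels/scipy/scikit-learn; each is cross-checked in the test suite
  against an independent oracle (hand step-up, exhaustive enumeration,
  exact linear systems, permutation).
- All randomness (simulation, bootstrap, subsampling) flows through
  `numpy.random.default_rng` seeds; the pipeline writes SHA-256 hashes of
  every artifact, and reruns with identical config and seed are
  byte-identical.

## Known limitations

- Single-block computation: the full gene × gene TOM is held in memory
  (~ n² doubles), comfortable to ~20,000 genes on a workstation; no
  block-wise approximation is provided.
- The dynamic cut is validated behaviorally, not bit-for-bit against any
  external tree-cut implementation; on real data the module count and
  grey fraction will differ between implementations.
- Stability matching by Jaccard can dilute consistency scores when a
  reference module fragments into near-equal halves.
- The deconvolution is a generic nonnegative least squares on a
  user-supplied signature; it does not model platform-specific probe
  effects and is intended to supply covariates, not precise cytometry.
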