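# Methods

This note documents the statistical model behind each stage, the
defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions a maintainer needs.

## Profile model and normalization

A profile is a strictly finite metabolites × samples matrix of
relative concentrations with a category per metabolite and a group
(region) per sample.  Zero or negative values are accepted in raw
profiles (MS-relative units can be arbitrarily scaled), but any
log-based operation validates positivity at call time.

Two row-wise normalizations are provided, both computed per metabolite
across **all** samples (not within group), so a heat map of the
normalized matrix colors each metabolite across every region on a
common scale:

* **z-score**: (x − mean)/s with the sample SD (ddof = 1); idempotent.
* **studentized residual**: the internally studentized residual of the
  per-metabolite mean model, (x − mean)/(s·√(1 − 1/n)).  This is the
  simplest residual model consistent with a per-metabolite location
  fit, and equals the z-score times the constant 1/√(1 − 1/n).

## Univariate screen

Concentrations are modeled as lognormal, so all location tests run on
log2-transformed values: on the raw scale a one-way ANOVA of
lognormal data with n = 6 per group is visibly miscalibrated
(empirical type-I ≈ 0.033 at nominal 0.05 in our simulations), while
on the log scale it is exact.  Log2 fold changes are nevertheless
always ratios of **raw** group means — a fold change of normalized or
logged values would not be a concentration ratio.

The screen is one-way fixed-effects ANOVA per metabolite with
Benjamini–Hochberg step-up adjustment across metabolites (default
cutoff q < 0.01).  Pairwise comparisons use Welch's t-test with
Satterthwaite degrees of freedom, two-sided, unadjusted at α = 0.05;
no post-hoc correction is applied across the pairwise family, matching
standard practice for descriptive per-pair annotation.

A metabolite is **characteristically high** in region g if, against
every other region, the Welch test is significant and the log2 fold
change is positive (low: all negative).  This all-pairs rule is the
strictest consistent reading of "high or low in a region" and makes
signatures region-exclusive; a more liberal any-pair rule is available
behind the `rule="any"` flag.

## PCA

PCA runs over samples with metabolites as features, on the z-scored
profile (MS intensities span orders of magnitude; standardization
prevents a few abundant compounds from dominating).  Loadings columns
are orthonormal; each is oriented so its largest-magnitude element is
positive, making output deterministic across LAPACK builds.  Top
loadings are ranked by |loading| with lexicographic tie-break.  An
optional metabolite subset supports running PCA on the significant set
only.

## Weighted correlation network

Pearson correlation (Spearman available) is computed across all
samples on log2 concentrations — correlation is invariant to the
z-scoring used elsewhere, but not to exponentiation, and the
generative model for concentrations is lognormal.

Adjacency is **unsigned**: a_ij = |s_ij|^β with zero diagonal.  The
literal signed power is available behind a flag, but with the default
odd β = 11 it produces negative adjacencies, which the connectivity
and overlap formulas cannot accept; the flag therefore clips at zero
with a warning.  β defaults to 11; `choose_beta` can instead select
the smallest power whose connectivity distribution fits
p(k) ~ k^−γ with R² ≥ 0.8 on a log–log regression of binned
frequencies (10 equal-width bins, empty bins dropped).

Connectivity is k_i = Σ_{u≠i} a_iu.  The topological overlap

    ω_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    l_ij = Σ_{u≠i,j} a_iu · a_uj,

is computed via one matrix product (the zero diagonal excludes the
u = i, j terms automatically), symmetrized, and clipped to [0, 1]
against floating-point drift.  D = 1 − Ω feeds complete-linkage
hierarchical clustering (SciPy's implementation; ties in random-valued
dissimilarities have measure zero, and SciPy's ordering is itself
deterministic).

**Branch cut.**  Candidate clusters are the connected subtrees below a
cut height; only candidates with strictly more than 10 members become
modules.  The cut height follows the joining-height-range convention
of the dynamic tree cut's "tree" method:

    h* = h05 + q · (hmax − h05),   q = 0.99 (configurable),

where h05 and hmax are the 5th percentile and maximum of the merge
heights.  The low-percentile anchor matters: on a topological-overlap
dendrogram of structureless data, merge heights pile up within ~1e-4
of 1, so h* lands below the bulk of those merges and pure noise yields
no candidate of meaningful size, while genuine co-varying branches —
which merge far below the background — survive intact.  (A cut at a
plain quantile of the merge heights always leaves ~1% of merges above
it and therefore always produces a handful of giant components
regardless of structure; a fixed absolute cut fails on dendrograms
whose height range does not reach it.  The range convention handles
both regimes and is what the published adaptive algorithm defaults
to.)  The adaptive/hybrid refinements of the published algorithm are
out of scope.

**Iteration.**  Detection repeats the whole chain (correlation →
adjacency at the *same* β → overlap → clustering → cut) on the not-yet-
assigned metabolites until an iteration yields no new module, an
iteration cap (10) is reached, or too few metabolites remain; the
leftovers are permanently unassigned.  β is chosen once on the full
set — re-selecting per iteration would redefine the network mid-
analysis.  The procedure contains no randomness.

**Module summaries.**  The eigen-metabolite is the first principal
component over samples of the z-scored member submatrix: unit-norm,
oriented so the mean correlation with members is non-negative, with
the fraction of member variance explained reported (bounded below by
1/|members| for standardized rows).  The hub is the member maximizing
the absolute correlation with the eigen-metabolite (kME).  kME lies in
[0, 1] and is the natural "connectivity to the module core" measure; a
raw adjacency row-sum would not be bounded by 1.  Region structure of
a module is assessed by one-way ANOVA of the eigen-metabolite scores
against group labels, and by pairwise member correlations computed
within each region's samples and over all samples merged (long-format
table for density/contour plotting).

Module names follow the conventional color order (turquoise, blue,
brown, …), assigned largest module first.

## Synthetic data generator

Log-concentrations follow

    x[m, s] = μ_m + δ[m, g(s)] + (module term) + (noise term)

with μ_m ~ Uniform(0, 4), and concentrations are exp(x) — lognormal,
strictly positive.  One `numpy` Generator seeded by a single integer
drives everything in a documented stream order (categories →
baselines → region effects → module factors → noise), so identical
seeds give bit-identical output and `planted_factors` can replay the
stream to expose the latent factors as an oracle.

* **Modules.**  Member m of module j has
  √λ·f[j, s] + √(1 − λ)·σ·ε; background metabolites have σ·ε, with
  f, ε ~ N(0, 1) and σ = `noise_sd`.  At σ = 1 the within-module
  correlation of log-values equals λ exactly, so the default
  λ = 0.8 plants modules with correlation 0.8 — the "highly
  correlated module" regime in which hub membership scores land in
  the 0.9+ range that real tissue modules exhibit.  A weaker
  parameterization (factor variance small relative to noise) was
  considered and rejected: modules with within-correlation ≈ 0.4 are
  mathematically invisible to a β = 11 network (adjacency ≈ 3·10⁻⁵
  against a comparable noise floor), so they would not emulate the
  phenomenon the network stage exists to detect.
* **Region effects.**  Each of the `n_affected` metabolites (drawn
  disjointly from module members, keeping the two screens separable)
  receives a contrast: one region shifted +`effect_size` and a second
  −`effect_size` on the log scale, in noise-SD units.  This is the
  region-characteristic "high here, low there" pattern; it also gives
  the ANOVA screen adequate noncentrality at the stated calibration
  point (a single-region shift of 2 SD has only ≈ 0.4 power at
  q < 0.01 with n = 6, which would make sensitivity targets
  meaningless).
* **Categories** are apportioned by largest remainder from
  configurable proportions (defaults: lipids 0.35, amino acids 0.25,
  the remaining six equal — the predominance pattern typical of brain
  tissue) and shuffled across metabolites.

Not emulated: batch effects, missing values, limit-of-detection
censoring, technical replicates, and heteroscedastic per-metabolite
noise.  Passing recovery tests on this generator demonstrates the
pipeline's correctness and calibration under the design's dimensions
and noise model, not robustness to MS artifacts.

## Problem sizes and tolerances

Default test and acceptance runs use the design scale itself (215 × 24)
plus: 12 000 simulated null metabolites for type-I calibration, 20
seeds for screen sensitivity, 10 seeds for eigen-factor recovery, 200
random adjacencies (n ≤ 8) against the triple-loop overlap oracle, 100
random dissimilarities (n ≤ 10) against a naive O(n³) agglomerator,
and 1000 random p-vectors against the literal step-up definition.
Exact-algebra comparisons use 1e-12 (1e-10 after iterated
floating-point pipelines); Monte-Carlo calibrations use the tolerance
their sampling error dictates (e.g. ±0.01 on a 0.05 rate at n = 12 000,
where the binomial SE is 0.002).

## Known limitations

* The branch cut is a single-height cut with the range convention, not
  the adaptive published algorithm; deeply nested module structure at
  very different tightness scales may be merged or missed.
* The pairwise Welch family is deliberately unadjusted; signature
  counts at α = 0.05 are descriptive, not inferential.
* With 24 samples, correlation estimates carry SE ≈ 0.2 near zero;
  modules with true within-correlation below ≈ 0.6 are not reliably
  detectable at β = 11, a property of the method, not the
  implementation.
* `eigen_region_anova` treats eigen-metabolite scores as data; the
  uncertainty from estimating the component is ignored, as is
  conventional.
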