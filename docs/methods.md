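# Methods

This note documents the models implemented in `agingnet`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer should know about.

## Preprocessing

**Depth filter.** Samples with library size (column sum) below
`min_library_size` (default 4,000,000 reads) are removed; the boundary is
inclusive.

**Outlier removal.** A sample network is built on the post-filter VST
matrix: Pearson correlation r between sample columns, adjacency
((1 + r)/2)², connectivity K_i = Σ_{j≠i} A_ij, standardized to z.K.
Samples with |z.K| > 2 (both tails; the criterion is on the magnitude of
the deviation) are removed and the gene filter + VST are recomputed on the
remaining samples. With fewer than 3 samples the distribution of K is
meaningless and the operation refuses to run; if sd(K) is zero (to within
1e-12 relative tolerance, guarding against floating-point noise on exactly
equal columns) nothing is flagged.

**Gene filter.** A gene is kept if its count is strictly greater than
`low_count` (default 10) in at least n samples, with n the tissue's minimum
age-group size. The alternative reading of the filter — row total > 10 —
is available as `mode="row_total"`.

**Normalization.** Median-of-ratios size factors: per-sample median, over
genes with all-positive counts, of count / per-gene geometric mean. The
median is taken on the ratio scale directly (an even number of genes
interpolates arithmetically, not geometrically).

**VST.** For the NB mean–dispersion trend α(μ) = a1/μ + a0, the variance of
a normalized count q is v(q) = (1 + a1)·q + a0·q²; the closed-form
antiderivative of 1/√v rescaled to base 2,

    vst(q) = log2( (1 + a1 + 2·a0·q + 2·√(a0·q·(1 + a1 + a0·q))) / (4·a0) ),

approaches log2(q) + const for large q and is strictly monotone in the
count. (a0, a1) are fitted by a robust (Huber) regression of per-gene
method-of-moments dispersions on 1/mean, with non-negative clamps (a
non-positive intercept is floored at 1e-8 with a warning). This is a
deliberate, documented simplification relative to gamma-GLM dispersion
machinery: the contract is the variance-flattening property (per-octave sd
ratio < 2 across means 2²..2¹² where plain log2(c+1) leaves > 2.5×), not
value-identity with any particular implementation. A `log2p1` mode
computes log2(count/size_factor + 1).

**PCA.** On the 500 genes of highest row variance, genes centered but not
scaled (common RNA-seq practice; unit scaling available via `scale=True`),
sample scores from the SVD of the centered submatrix.

## Segmented regression

Model per gene: y = β₀ + β₁·t + Σⱼ δⱼ·(t − bⱼ)₊ + γ·sex + ε — a continuous
hinge basis, so segment slopes are cumulative sums sⱼ = β₁ + δ₁ + … + δⱼ.
Sex enters as a single additive binary covariate shared across segments
(the smallest model consistent with "adjusting for sex"; a sex×time
interaction is not fitted). If sex is constant in a tissue the covariate is
dropped to avoid collinearity.

Breakpoint candidates are the interior distinct observed ages: on a 9-point
grid an exhaustive search over all placements (subject to
`min_per_segment` samples per segment; a sample at exactly a breakpoint
counts toward the left segment) is exact and cheap, so no continuous-search
estimation is needed. Per k the minimum-RSS placement is kept; across
k = 0..`max_k` (default 8) the Gaussian-profile BIC
n·ln(RSS/n) + p·ln(n) decides, with p the number of fitted coefficients.
RSS is floored at 1e-12 × TSS so that ties at zero residual resolve to the
smaller model — exactly linear data always select k = 0. Placements whose
design matrix is rank-deficient are skipped.

Internally all genes are fitted at once: for each placement the QR-based
residual projector is formed once and applied to the full expression
matrix. This is what makes the permutation calibration affordable
(~2,000 genes × 10 permutations × ~130 placements in seconds).

**Cutoff calibration.** The sample→age assignment is permuted globally
(each sample keeps its sex), all genes are refitted, and the pooled null
adjusted-R² values give the cutoff as their (1 − pass_fraction) quantile
(default pass_fraction 0.01, n_perm 10 — the permutation count is a
package default; the 'higher' quantile convention guarantees the null pass
fraction never exceeds the target). A gene is top dynamic if adj R² >
cutoff (strict) and min segment-slope p < 0.1. Segment directions are
called flat when the slope p ≥ 0.1 (the same α reused as the flatness
threshold), otherwise the slope's sign.

**Summaries.** Breakpoints of the selected genes are pooled into a
histogram over the age grid with the median and the fraction at or before a
reference age (default 15 months). Cross-tissue breakpoint distributions
are compared with a tie-corrected Kruskal–Wallis test followed by Dunn's
pairwise z-tests (tie-corrected SE; Holm adjustment by default,
configurable). Biotype composition of the selected genes is tested per
biotype with a two-sided Fisher exact test on the 2×2 table against the
reference annotation (a chi-squared mode exists for comparison), BH
adjusted across biotypes.

## Co-expression network

**bicor.** For each gene, u = (x − med(x))/(9·MAD(x)), weights
(1 − u²)²·1[|u| < 1], and the correlation of the weighted deviations.
Genes with zero MAD fall back to Pearson for every pair they join
(per-variable fallback). Zero-variance genes must be removed first.

**Soft power.** Signed adjacency A = ((1 + r)/2)^β. For each candidate β
the connectivity distribution is binned (~10 equal-width bins) and log10
frequency is regressed on log10 mean connectivity; the fit index is R²
signed so that only decaying distributions score positively. The chosen β
is the smallest reaching 0.8; otherwise a documented fallback keyed on
sample count applies (< 20 samples: 16; 20–29: 14; 30–39: 12; ≥ 40: 9).
Per-tissue powers used in the original study ship as config defaults.

**TOM.** TOM_ij = (L_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij) with
L_ij = Σ_{u≠i,j} a_iu·a_uj, unit diagonal; 1 − TOM is the clustering
dissimilarity.

**Module detection.** Average-linkage hierarchical clustering of 1 − TOM
with a static cut at a `deep_split`-preset fraction of the maximum merge
height ({0: 0.99, 1: 0.95, 2: 0.90, 3: 0.85, 4: 0.80} — higher preset,
finer clusters). Clusters below `min_module_size` (50) go to the reserved
grey label. A cohesion cleanup then releases to grey any gene whose
correlation with its module eigengene is below 0.3 — this stands in for
the pruning behavior of the hybrid dynamic tree cut, whose exact algorithm
is deliberately not replicated; the contract is recovery of planted
structure (adjusted Rand index ≥ 0.8 on equicorrelated blocks), not label
identity with any reference implementation. Modules whose eigengene
dissimilarity 1 − cor(ME_a, ME_b) < 0.15 are merged iteratively until
stable, and final labels are size-ordered (M1 largest).

**Eigengenes and trait statistics.** ME = first right-singular vector over
samples of the module's z-scored expression, unit norm, sign-oriented to
correlate positively with the module mean profile. Module–trait
association uses bicor with the Student-t approximation for p
(t = r·√((m−2)/(1−r²))) and BH FDR per trait across modules; selection
requires |bicor| ≥ 0.5 and FDR < 0.05 (the magnitude criterion keeps
negatively age-correlated modules). MM is the signed Pearson correlation
of a gene with its module's ME; GS the absolute correlation with the
trait. A module is retained when cor(|MM|, GS) ≥ 0.5 with p < 0.05; hub
genes have GS > 0.2 and MM > 0.8 (strict inequalities).

The network is built in a single block: at the scales this package targets
(10³–10⁴ genes) the full TOM fits in memory, so block-wise decomposition
is out of scope.

## Integration, enrichment, enrichment map

The per-tissue signature is the union over selected (and MM–GS-retained)
modules of (top dynamic ∩ hub). Sex-associated modules join the
integration only when listed in `trended_sex_modules` — whether a sex
module shows a time trend is an explicit configuration judgement, not an
automated rule. Three-set and cross-tissue overlaps are reported as
exclusive (upset-style) regions.

ORA is the one-sided hypergeometric upper tail P[X ≥ k] on term
memberships intersected with the expressed-gene universe, restricted to
within-universe term sizes 10–500 (exposed), BH FDR, significance at
FDR < 0.05. GO ancestor propagation is assumed baked into the input GMT.

The enrichment map connects significant terms whose gene-set similarity
(overlap coefficient |A∩B|/min(|A|,|B|) by default; jaccard and a 50/50
combination are selectable) reaches 0.7, using full within-universe term
sets (hit-only sets are a config alternative). MCL runs on the
column-stochastic similarity matrix with self-loops at each node's maximum
incident weight, inflation 2.0, pruning below 1e-5, convergence at 1e-6 or
100 iterations; clusters are the connected components of the attractor
support. Cluster labels take up to 4 words greedily by score = name-wise
occurrence count + 8 × adjacencies to already-selected words; English
function words and bare ontology boilerplate are stopworded but domain
words such as "regulation" are kept, since real labels use them. Each
cluster collapses to a meta-node whose summary FDR is the minimum member
FDR (the "most significant" reading; median aggregation would be a
one-line change), with meta-edges carrying mean cross-cluster similarity.

## Synthetic data

The generator emulates a multi-tissue aging study design at desk scale:
9 ages (3–27 months, step 3) × 2 sexes × 2 replicates = 36 samples, 1,200
genes by default (700 background, 200 single-breakpoint trajectory genes,
two 100-gene age modules and one 100-gene sex module). Counts are NB with
μ_gs = sf_s·exp(b_g + f_g(t_s) + γ_g·sex_s + λ_g·e_m(t_s) + ε) and
α(μ) = 2/μ + 0.05; library sizes are log-normal around 8M reads with two
planted shallow samples (< 4M expected) and one outlier sample whose gene
labels are permuted (preserving depth, destroying correlation — the exact
failure mode z.K detects). Trajectory genes use hinge slopes of 0.25
natural-log units/month with sign flips at the breakpoint, large enough
that the slope change exceeds three residual sds per 3-month grid step.
Module loadings λ are solved from the target within-module correlation
(default 0.6) against the approximate log-scale noise floor a0 + σ_ε²;
hub genes carry 1.6× the base loading. Planted GMT terms are composed 60%
of a module's hub genes.

What it does **not** emulate: gene-length or GC effects, empirical
mouse-gene abundance distributions, batch structure, unbalanced sex
designs, or count sparsity at single-cell depths. Passing tests therefore
demonstrate correctness of the algorithms and sane behavior at realistic
effect sizes — not that any particular real dataset will yield the same
module count or gene lists.

## Numerical choices and limitations

- All randomness flows through `numpy.random.default_rng(seed)`; every
  pipeline stage is a pure function of (inputs, config, seed), and module
  detection has no randomized steps at all.
- BIC ties resolve to the smaller k (placements are enumerated in
  ascending k); the RSS floor makes this deterministic at zero residual.
- Correlation p-values use the Student-t approximation also for bicor and
  for point-biserial (binary-trait) cases, matching common practice.
- The static-cut approximation of dynamic tree cut maps deep_split 0–4 to
  fixed cut-height fractions; deep_split 4 only approximates the hybrid
  algorithm's most sensitive setting.
- The problem sizes used throughout the validation suite (1,200–2,000
  genes, 36 samples, 10 permutations) were chosen as the smallest designs
  that exercise every selection threshold with comfortable margins.
- Expression trajectories are planted on the log-mean scale, so VST-space
  shapes are only approximately the planted piecewise-linear functions;
  recovery tolerances (±one grid step) account for this.
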