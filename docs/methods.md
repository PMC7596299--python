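# Methods

This note documents the models and procedures implemented in
`coexnet`, the parameters that matter, the numerical choices made where
the design was genuinely open, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## Normalization and quality control

**Size factors.** Library depth is removed with the median-of-ratios
estimator: for each gene whose geometric mean count across samples is
positive, form the ratio of each sample's count to that geometric mean;
a sample's size factor is the median of its ratios. No rescaling
convention is applied afterwards — for balanced data the geometric mean
of the factors is already ≈ 1. Two consequences worth knowing: the
factors are invariant to a global rescaling of all counts (numerator
and reference scale together), and scaling one sample by c changes its
factor by exactly `c^(1−1/m)` (m = number of samples) because the
per-gene reference moves too. When every gene contains a zero somewhere
there is no usable reference gene; an optional pseudo-reference (the
geometric mean over nonzero counts only, `pseudo_reference=True`)
rescues such datasets and is off by default.

**Low-expression filter.** A gene is dropped only if its median raw
count is below 10 in *every* condition group. The per-condition test
keeps genes expressed only under particular conditions, which is the
point of a multi-condition compendium. The filter runs on raw counts,
before the log transform; it is idempotent.

**Transform.** `log2(count / size_factor + 1)`. No variance-stabilizing
transform beyond the log; correlation downstream is robust (bicor), so
residual mean-variance coupling is tolerated.

**Outlier libraries.** Each sample's mean pairwise Spearman correlation
with all other samples is standardized across samples; samples below
z = −2.5 (configurable) are dropped. Spearman makes the flag invariant
to monotone per-sample distortions (platform effects change scale, not
order). With fewer than 4 samples the score is meaningless and an error
is raised.

**Batch correction.** Per gene, each batch's mean is subtracted and the
global gene mean restored. This removes additive (log-scale) batch
offsets exactly and leaves within-batch covariance untouched — the
simplest correction consistent with libraries pooled from different
sequencing technologies. Single-sample batches cannot be corrected this
way and are left alone with a warning. Nonlinear batch distortions are
out of scope.

## Network construction

**Biweight midcorrelation.** Deviations from the median are scaled by
9×MAD, where the MAD is used *raw* (no 1.4826 consistency constant),
matching the form of the weighting usually cited for this statistic;
observations at or beyond 9 MADs get zero weight via the Tukey biweight
`(1 − u²)²`. A vector with MAD = 0 (more than half its values tied) has
undefined weights and falls back to median-centered Pearson; such genes
are recorded on the correlation object. The matrix version is a single
matrix product of the weighted, unit-normalized rows, so it agrees with
the pairwise definition to machine precision. Constant gene rows are a
hard error — the filter should have removed them.

**Adjacency and mode.** Default mode is *unsigned*, `a = |r|^β`, which
lets anticorrelated genes share a module; the *signed* transform
`((1+r)/2)^β` is available by flag. Default β = 12.

**Scale-free fit.** Connectivities are binned into 10 equal-*width*
bins; log10 bin frequency is regressed on log10 bin mean connectivity
over non-empty bins. R² is reported unsigned (it is a squared
correlation); the slope's sign is checked separately when choosing β:
the chosen β is the smallest grid value (default 1..20) with R² ≥ 0.9
and negative slope. Equal-count binning would make every bin frequency
identical and the regression degenerate, which is why equal-width bins
are used. Fewer than two usable bins, or all-equal connectivities, are
errors.

**Topological overlap.** Standard unsigned TOM with the diagonal set
to 1 and `diss = 1 − TOM` as the clustering dissimilarity. The
shared-neighbor sum is computed with a zero-diagonal matrix product,
which excludes u ∈ {i, j} exactly.

## Module detection

**Tree.** UPGMA (average linkage) on the TOM dissimilarity via scipy;
deterministic, ties resolved by cluster index.

**Adaptive cut.** Weighted-network join heights compress toward 1, so
a static cut is placed at 99% of the span between the 5th percentile
and the maximum of the join heights (not of the absolute height — an
absolute cut slices through tight modules whenever the height range is
narrow). Branches below the cut are then recursively split while both
children hold at least `min_module_size` (default 40) leaves and each
child's core (mean internal) dissimilarity sits at least 10% below the
parent's; the 10% gap (`core_gap`) is the split-sensitivity knob —
smaller values split more aggressively. Remaining branches of
sufficient size become modules; everything else is grey. Finally,
grey genes are adopted by the module with the smallest mean
dissimilarity to them, provided that mean falls below the module's
90th-percentile internal dissimilarity (`reassign_grey=True` by
default). This is a deterministic approximation of hybrid dynamic tree
cutting, not a byte-level replica of the reference R implementation.

**Labels.** Modules take names from a fixed color list by decreasing
size, ties broken by smallest member gene ID, so labels are comparable
across runs; `grey` is reserved for unassigned genes.

**Eigengenes.** First right singular vector of the z-scored member
rows, unit norm, sign-oriented to correlate non-negatively with the
module's mean standardized profile. Zero-variance members are excluded
with a warning; variance explained is `s₁²/Σsₖ²`.

**Merging.** Eigengenes are clustered with average linkage on
`1 − cor`; groups joined strictly below the merge cut height (default
0.25, i.e. eigengene correlation above 0.75) merge, eigengenes are
recomputed, and the procedure iterates to convergence. Strictness at
the boundary makes a cut height of 0 an exact identity. Grey never
merges. The module count is non-increasing and the result idempotent
under re-merging at the same threshold.

## Interpretation statistics

**Enrichment scoring.** For each (module, binary feature) pair a 2×2
chi-squared test without continuity correction is computed over the
universe of all genes carrying a module assignment, grey included as a
module of its own. Direction is enriched or depleted according to the
sign of observed minus expected in-module feature count. Each predictor
contributes +1/−1 at p < 0.05 and +2/−2 at p < 10⁻⁵; a condition's
score sums its predictors' contributions. Raw p-values are the default
(the scoring scheme is conventionally applied uncorrected);
Benjamini–Hochberg correction and a Fisher-exact variant are available
by flag. Degenerate tables (empty module or feature) score 0.

**Concordance.** Over the genes present in both the module partition
and the external clustering: statistic 1 counts genes sharing both
their external cluster and their module with at least one other gene;
statistic 2 counts genes lying in the unique module holding the
plurality of their external cluster (ties disqualify the whole
cluster — a deliberate, literal reading of "the single best module").
Both are invariant to relabeling either partition. The null permutes
module labels over assessable genes; the empirical one-tailed p is
`(1 + #{perm ≥ obs})/(n_perm + 1)`, and a one-tailed chi-squared
approximation on the concordant/non-concordant split against the
permutation-mean expectation is reported alongside. Caveat: with few,
large modules statistic 1 saturates (nearly every gene shares a module
with a cluster-mate even after permutation), so its permutation p is
uninformative in that regime; statistic 2 keeps a usable null. Both are
reported so the regime is visible.

**Preferential distribution and repartition.** Per external cluster,
the unique-plurality module (or "tied"); per curated category, a
cross-tabulation against module assignment with genes lacking a module
reported separately, so row sums equal category sizes among
module-assigned genes.

## Synthetic data generator

The generator emulates a multi-study bulk RNA-seq compendium at desk
scale. Defaults: 1,200 genes × 36 samples, 3 condition groups crossed
with 2 batches, 5 planted modules of 40–80 genes, one outlier library.
Per module, a latent per-sample factor (unit variance, cross-module
correlation 0.1) receives condition-specific mean shifts (sd 1.0).
A member gene's log-mean is
`base + σ·(√ρ·factor + √(1−ρ)·noise)`, with σ = 1.0 and ρ = 0.7, so two
members correlate at ρ on the log scale before count noise — "module
correlation 0.7" therefore refers to the pairwise correlation, not the
per-gene loading (√0.7). Background genes carry independent variation
of the same magnitude. Gene baselines are log-normal (median ≈ 150
counts), library sizes log-normal (σ = 0.25), batch offsets additive
per gene (sd 0.5 log units), and counts negative-binomial with
dispersion 0.1 (`var = μ + 0.1μ²`). Outlier libraries are produced by
permuting a sample's counts across genes, which preserves its marginal
distribution while destroying its profile. Annotation features are
Bernoulli with baseline prevalence 0.1 and odds multiplied by 8 inside
the target module; the external clustering splits each planted module
into 3 sub-clusters and reassigns 10% of genes at random. Everything is
a pure function of the configuration and seed.

The defaults were chosen so the full pipeline (correlation through
merging, 1,200 genes) completes in a couple of seconds, making
20-seed recovery studies cheap. What the generator does *not* emulate:
gene-length and GC effects, nonlinear batch distortions,
platform-specific error models, zero-inflation beyond what the
negative binomial produces, and correlated annotation predictors.
Passing recovery tests therefore demonstrates that the implementation
recovers the structure its own model plants — not that the pipeline is
robust to every artifact of real compendia.

## Numerical conventions

Correlations are clipped to [−1, 1] and symmetrized; TOM is clipped to
[0, 1] and symmetrized; eigengene sign is fixed by the module mean;
axis signs of the classical MDS embedding are fixed by the
largest-magnitude coordinate. Merging uses a strict inequality at the
cut height (tolerance 1e-12). Table exports carry 10 significant
digits and round-trip losslessly at that precision. All stochastic
steps (generator, permutation nulls) take explicit seeds; identical
configuration and seed reproduce outputs bit-for-bit.

## Limitations

Dense O(n²) memory: correlation, adjacency and TOM matrices are held in
full, which is comfortable to ~10–20k genes on a workstation but not
beyond; no sparse or approximate path is provided. The tree cut is an
approximation of the reference hybrid algorithm and will not reproduce
its output gene-for-gene. The chi-squared approximation for the
concordance null relies on the permutation-mean expectation; at small
counts the permutation p is the one to trust. Detection assumes modules
occupy a minority of an incoherent background or are mutually
separated; a dataset that is one single module throughout has no
background to contrast against and will be reported as largely grey.
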