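# coexnet

Weighted gene co-expression network analysis for bulk RNA-seq count
compendia, with the downstream statistics needed to interpret the
resulting modules. The package was built for the kind of study that
assembles a hundred-plus public RNA-seq libraries for one organism
(e.g. a diatom grown under different nutrient stresses, sequenced by
different labs on different platforms), infers modules of co-expressed
genes, and then asks what each module does — which annotations are
enriched in it, how well it agrees with older co-regulation resources,
and how curated gene sets (organelle pathways, transcription-factor
families) distribute across modules.

## What it computes

Starting from a raw gene × sample count matrix with per-sample
condition and batch labels:

1. **Ingest** — median-of-ratios size factors (the DESeq2 estimator),
   removal of genes whose median raw count is below 10 in every
   condition, `log2(count/s + 1)` transform, outlier-library flagging
   from mean pairwise Spearman correlation, per-batch gene-mean
   centering.
2. **Network** — biweight midcorrelation `bicor(x, y)` between all gene
   pairs (Tukey biweights on 9-MAD scaled deviations from the median);
   soft-thresholded adjacency `a_ij = |r_ij|^β` (unsigned, default) or
   `((1+r_ij)/2)^β` (signed); connectivity `k_i = Σ_{j≠i} a_ij`; the
   scale-free topology fit index R² (squared correlation of
   log p(k) vs log k over connectivity bins) used to choose β, default
   β = 12; and the topological overlap matrix
   `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`.
3. **Modules** — average-linkage (UPGMA) clustering of `1 − TOM`, an
   adaptive tree cut with minimum module size 40, module eigengenes
   (first principal component of the standardized member rows), and
   iterative merging of modules whose eigengenes correlate above 0.75
   (merge cut height 0.25). Hub genes, per-module expression quartiles,
   classical MDS coordinates and Cytoscape-ready edge lists
   (|r| > 0.20) summarize each module.
4. **Interpretation** — 2×2 chi-squared enrichment/depletion of binary
   gene annotations per module, scored +1/−1 at p < 0.05 and +2/−2 at
   p < 10⁻⁵ and summed over the predictors of a condition; two
   concordance statistics against an external gene clustering (genes
   sharing a module with a cluster-mate; genes in their cluster's
   unique plurality module) with permutation and chi-squared nulls;
   preferential distribution of external clusters over modules; and
   repartition (cross-tabulation) of curated gene sets.

A seeded generator (`coexnet.simulate`) produces negative-binomial
count matrices with planted modules, batch offsets, outlier libraries,
planted annotation enrichments and a noisy external clustering, so the
whole pipeline is testable without any external data.

## Worked example

The four numbered scripts under `analysis/` run the full study on
synthetic data (seed 7 shown; every step is deterministic given the
seed):

```sh
$ python analysis/01_simulate.py
simulated 1200 genes x 36 samples (seed 7)
planted modules: {'M1': 78, 'M4': 76, 'M3': 68, 'M2': 65, 'M5': 63}; background genes: 850
outlier samples planted: ['s028']

$ python analysis/02_network.py
ingest: kept 1198/1200 genes (median-count filter), dropped outlier samples ['s028']
  planted outliers recovered: ['s028'] of ['s028']
network: smallest beta reaching R^2 >= 0.9 is 7; at beta=12 the fit is R^2=0.907 (slope -1.09)

$ python analysis/03_modules.py
tree cut found 4 modules; eigengene merging at 0.25 left 4 (sizes {'turquoise': 136, 'blue': 80, 'brown': 77, 'yellow': 68})
adjusted Rand index vs planted truth: 0.956

$ python analysis/04_interpret.py
enrichment: scored 5 modules x 8 features; 7 cells at strength |2| (planted features should light up their own module)
concordance over 349 assessable genes: 330 (95%) share a module with a cluster-mate (perm p=1); 330 (95%) sit in their cluster's plurality module (perm p=0.001)
preferential distribution: 15/15 clusters prefer a single module
```

Reading the output: the one planted outlier library is caught by the
Spearman QC; β = 12 satisfies the scale-free criterion (R² = 0.907 with
a negative slope); the tree cut recovers the planted modules (two
planted modules whose latent factors drifted together merge into
`turquoise`, which is exactly what eigengene merging is for; the
adjusted Rand index against the planted truth is 0.956); and each
planted annotation feature scores +2 in its own module. The plurality
concordance statistic is far above its permutation null (p = 0.001);
the shared-module statistic saturates under permutation at this module
count, which the methods note discusses.

The same pipeline is scriptable via the `coexnet` CLI
(`simulate`, `net`, `modules`, `interpret`, `export`, `run`) or the
`coexnet.pipeline.run_pipeline` function, which writes every artifact
plus a manifest recording parameters, input hashes and QC warnings.

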