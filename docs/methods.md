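# Methods

This note documents the models, estimators and numerical choices behind
`sedabench`, in the spirit of the model documentation that simulation and
statistics packages ship alongside their code.

## Community simulator

The generator is a gamma/log-normal → negative-binomial hierarchy:

* Each taxon *j* draws a baseline log-mean abundance
  `b_j ~ Uniform(-2, 2)` (natural log, relative scale — the matrix is
  renormalized per sample, so only differences matter).
* A fraction `de_prob ~ Uniform(0.1, 0.4)` of taxa is differentially
  abundant. In **cluster** mode every cluster draws its own
  differential set; each affected taxon's log-mean shifts by
  `± log(f_j)` with fold factor `f_j ~ Uniform(2, 6)` and a fair sign.
  In **path** mode each sample draws a position `t_i ~ Uniform(0, 1)`
  and differential taxa have log-abundance linear in `t_i` with slope
  `± log(f_j)` — the simplest monotone gradient.
* Per-sample library sizes are log-normal with mean
  `library_size_mean ~ Uniform(2·10⁴, 10⁵)` reads and coefficient of
  variation `~ Uniform(0.1, 0.4)` — typical post-filtering depths for
  metabarcoding studies.
* Counts are negative-binomial with `var = μ + φ μ²`,
  `φ_j ~ Uniform(0.1, 1.0)` (moderate to strong overdispersion, the
  range usually estimated from amplicon data).

Defaults: 100 samples × 400 taxa, 5 equal clusters. Per-run scalars are
drawn fresh from the ranges above under the run's seed, so a batch of
runs spans a family of related but distinct communities. The generator
deliberately does **not** model PCR/sequencing error, chimeras, batch
effects, or zero inflation beyond what the NB produces; conclusions
about those artefacts cannot be drawn from these tests.

Synthetic per-taxon annotations are produced by a Kingman-style
coalescent (pairwise exponential merge times) and Jukes–Cantor sequence
evolution along the branches (default 150 bp, 0.5 substitutions per site
per unit time). Only the *relative* similarity structure matters for the
k-mer, PINA and UniFrac methods, which is all this process provides; it
is a synthetic stand-in, not a model of any real marker. Rank-mapping of
user-supplied reference sequences (most abundant sequence → most
abundant taxon, ties by taxon id) is available as an alternative.

## Ancient-DNA degradation model

Degradation is modelled purely as taxon dropout with depth preservation:

* Effect levels {0, 0.25, 0.50, 0.75} are assigned to exactly a quarter
  of samples each (remainder round-robin in that order), balanced within
  every class in cluster mode and at random along gradients.
* For a sample at level *e*, `round((e + U(-0.03, 0.03)) · n_detected)`
  of its detected taxa — chosen uniformly — are set to zero. The jitter
  half-width of 0.03 is the "small random noise" around the target.
* The removed reads go to a uniformly chosen nonempty subset of the
  sample's top decile by **pre-dropout** abundance (`max(1,
  ⌊0.1·n_detected⌋)` taxa; if all of them were dropped, the surviving
  taxa's top decile is used instead), proportionally to pre-dropout
  abundance with largest-remainder rounding. Row sums are therefore
  conserved as exact integers.

This captures the "false negatives + depth is an instrument setting"
view of sedaDNA. It does not model damage chemistry (deamination,
fragmentation), false positives/tag jumps, or community turnover over
time — degraded samples keep their true label/gradient value.

## Count transformations

Thirteen methods behind one dispatcher. Notable implementation choices:

* **clr** adds a pseudocount of 1 to every cell by default (configurable);
  **rclr** centres on the geometric mean of the nonzero entries and
  leaves zeros at zero.
* **CSS** picks its quantile by scanning the per-sample nonzero-count
  quantile curves against their across-sample median and choosing the
  smallest p ≥ 0.5 where the median absolute deviation grows by more
  than 10 % per grid step (fallback 0.50). Output is counts divided by
  the per-sample cumulative-sum factor, rescaled by the median factor.
* **VST** uses median-of-ratios size factors (positive-count geometric
  mean reference), method-of-moments taxon dispersions, a least-squares
  `φ(μ) = a/μ + b` trend, and the closed-form NB variance-stabilizing
  map `log2((1 + a + 2bq + 2√(bq(1+a+bq)))/(4b))`.
* **TMM / TMMwsp** follow the edgeR 4.0 reference implementation —
  doubly-trimmed (30 % on M, 5 % on A) precision-weighted mean of
  M-values against an automatically chosen reference sample; the
  singleton-pairing variant pairs taxa positive in only one of the two
  samples largest-against-largest. Both variants were verified against
  edgeR to < 10⁻⁸ on dense and sparse matrices, and a live cross-check
  against edgeR runs in the test suite. Factors are applied as
  effective-library-size log2-CPM.
* **wrench** is a deliberately simplified variant of the published
  estimator: log ratios of sample proportions to the mean proportion
  profile, averaged over detected taxa, shrunk toward the group mean by
  an inverse-variance weight, times a detection-fraction hurdle term.
  It preserves the estimator's structure (group-aware, hurdle-corrected,
  log-normal shrinkage) without the full empirical-Bayes machinery.
* **GMPR** size factors are geometric means of median pairwise count
  ratios over shared nonzero taxa.
* **k-mer** profiles (default k = 5) are abundance-weighted sums of
  per-taxon k-mer frequency vectors, renormalized to proportions.
* **Rarefaction** uses exact multivariate hypergeometric sampling to the
  minimum sample total by default.

## Beta-diversity indices

Formula-based indices (Bray–Curtis, Canberra, Kulczynski, Morisita–Horn,
Gower, alt-Gower, Chao, Pearson, Spearman, Euclidean) follow the vegan
formulations and were verified against `vegdist` to < 10⁻⁸; brute-force
double-loop oracles are kept in the test suite. The Chao index is the
abundance-based Jaccard dissimilarity with the unseen-shared-species
correction (with the doubleton count floored at 1), and always operates
on raw integer counts regardless of the upstream transform.

* **RF proximity** trains an *unsupervised* random forest (real samples
  vs a column-permuted synthetic copy) and uses 1 − leaf-co-occurrence
  frequency; benchmark labels are never shown to the forest, so the
  PERMANOVA downstream is not circular. A supervised variant would leak
  the target into the distance.
* **TINA/PINA** compute the association-kernel cosine of the two
  samples' relative abundance vectors: `s(A,B) = wᴬᵀ K wᴮ /
  √(wᴬᵀKwᴬ · wᴮᵀKwᴮ)`, with K the taxon association matrix — Spearman
  correlation across samples rescaled to [0, 1] for TINA, `1 −
  cophenetic/max` for PINA. Constant taxa get association 0.5 with a
  warning. With K = I this reduces to cosine dissimilarity; disjoint
  communities are at distance 1.
* The **UniFrac family** operates on per-branch relative abundance
  masses: normalized weighted UniFrac; the generalized form with
  α = 0.5 (α = 1 recovers weighted, verified); and the
  variance-adjusted weighted form that down-weights branches whose
  abundance mass is near 0 or 2. Weighted UniFrac is verified against
  scikit-bio. Inputs are renormalized to relative abundances per sample;
  transforms with negative outputs are refused.

A compatibility table (editable) declares which transforms can feed
which index: log-ratio/VST/TMM outputs only feed Euclidean, correlation
and RF distances; k-mer features cannot feed taxon- or tree-aware
indices; Chao is run once on raw counts (listed under rarefy/prop to
avoid duplicate work).

## Ordination

* **PCoA**: double-centring and eigendecomposition, top-2 positive
  eigenvectors scaled by √λ, deterministic sign convention, no
  Cailliez/Lingoes correction — negative-eigenvalue mass is reported in
  the diagnostics instead.
* **NMDS**: nonmetric SMACOF — Guttman transform alternating with
  isotonic regression of configuration distances on dissimilarity ranks
  — minimizing Kruskal stress-1; 20 random restarts by default (4 in the
  scaled-down pipeline test), best stress kept, stress recomputed on the
  returned configuration so the reported value matches an independent
  recomputation exactly.
* **t-SNE** (scikit-learn) and **UMAP** (umap-learn) run on precomputed
  distances with fixed seeds; perplexity defaults to
  `min(30, ⌊(n−1)/3⌋)` and n_neighbors to 15, both auto-shrunk with a
  warning when infeasible. Their contract here is seeded determinism and
  2-D output, not internal math. Note that UMAP's `min_dist` (default
  0.1) enforces a minimum separation even between identical samples; set
  it to 0 when exact co-location matters.
* `embedding_distance` returns plain Euclidean distances between the
  2-D coordinates. Per-axis z-scoring is available behind a flag but off
  by default, so that PCoA of a Euclidean configuration reproduces its
  input distances; the machine-learning feature builder z-scores its
  feature columns itself, which is where scale actually matters.

## PERMANOVA, betadispersion, and the grid

The pseudo-F implements the McArdle–Anderson partition: with
`G = −½ J D² J` and hat matrix `H` from the design (cluster indicators,
or intercept + one continuous regressor with df = 1),
`F = (tr(HGH)/df_model) / (tr((I−H)G(I−H))/df_resid)`. Significance is by
free permutation, `p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`, default
n_perm = 999. Verified against two independent oracles (group
sum-of-squares form; explicit centring/projection) and scikit-bio, and
calibrated: under the null the empirical type-I error at α = 0.05 sits
inside the 95 % binomial interval over 500 Monte Carlo replicates.

Betadispersion embeds the distance matrix by full PCoA, keeps negative-
eigenvalue axes as imaginary coordinates whose squared contributions are
subtracted, computes each sample's distance to its group centroid, and
returns the one-way ANOVA F on those distances (verified against vegan's
`betadisper(..., type = "centroid")`).

The grid runner scores every compatible (transform, index[, ordination])
combination on every (modern, ancient) dataset pair, caching the
distance matrix across ordinations, and ranks combinations by median
pseudo-F (ties: mean F, then combination name).

## Transfer functions

Features are either the full transformed composition matrix or the 2-D
coordinates of a **joint** ordination of modern + ancient samples (NMDS
and PCoA have no out-of-sample projection, so joint embedding is the
only construction that treats all four ordinations uniformly). Fitted
transforms (CSS/VST/TMM/wrench/GMPR factors) are likewise fitted on the
stacked matrix, mirroring a single matrix per dataset. Feature columns
are z-scored.

KNN tunes k over {1, 3, 5, 7, 9, 11} by repeated stratified 10-fold CV
(10 repetitions; fold count auto-shrunk when a class is smaller than the
fold count) inside the 60 % training partition; RF runs untuned at 500
trees. Gradients are min-max normalized to [0, 1] before fitting so RMSE
is comparable across datasets. The transfer metric is computed by
training on all modern samples and predicting the ancient samples,
reported overall and per effect level. Tukey's HSD compares the pooled
top-5 approaches per (feature space × algorithm) at each effect level,
with a compact letter display (groups sharing a letter are not
significantly different at 0.05).

## Empirical-dataset preprocessing

In order: class balancing by subsampling to the smallest class;
subsampling to at most 125 samples; taxa reduction by subtracting a
single per-cell integer constant (found by bisection, floored at zero)
until the surviving taxon count falls in the 1000–4000 window; dropping
samples with fewer than 20 detected taxa. The per-cell constant is the
interpretation of "subtracting the same number of reads across the
matrix" that removes rare taxa while preserving per-cell dominance; note
it does *not* exactly preserve the rank order of all column sums (taxa
with many mid-sized counts lose more mass than taxa with few large
ones), which is inherent to the operation.

## Problem sizes used in the checks

The automated checks run at desk scale: oracle comparisons on 6 × 10
matrices; calibration with 500 replicates of 20 samples; the pipeline
check on five 50 × 200 five-cluster datasets with a strong-separation
setting (differential fraction 0.25–0.35, fold change 4–8) across a
3 × 4 × 4 grid of transforms × indices × ordinations with KNN transfer
(2 CV repetitions, 4 NMDS restarts). The full-size defaults (100 × 400,
30 + 30 matrices, 999 permutations, 10 CV repetitions, 20 restarts)
remain the package defaults.

## Known limitations

* wrench and VST are structural re-implementations, not drop-in
  replacements for the Bioconductor estimators; their outputs are
  validated by properties, not equivalence.
* The degradation model omits false positives, damage chemistry and
  community turnover; robustness results transfer to real sedaDNA only
  to the extent that dropout is the dominant artefact.
* TINA's association matrix uses rank correlation; compositionally
  aware association estimators (SparCC-style) are out of scope.
* Unweighted (presence/absence) UniFrac is intentionally absent; the
  benchmark concerns abundance-weighted indices.
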