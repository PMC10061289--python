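# Methods

This note documents the models and procedures `gliomune` implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about behavior on real data.

## Single-sample enrichment scoring

Immune cell abundance and pathway activity are scored per sample with the
ssGSEA running-sum statistic. For sample *j* with *N* rankable genes, genes
are ranked by expression with average ranks for ties (the top-expressed gene
carries rank *N*); walking the genes in descending order,

    ES(G, j) = Σ_{i=1..N} [ P_in(i) − P_out(i) ],
    P_in(i)  = Σ_{k≤i, g_k∈G} ρ_k^α / Σ_{g∈G} ρ^α,
    P_out(i) = #{k ≤ i, g_k ∉ G} / (N − |G|).

* **α = 0.25**, the conventional ssGSEA weight; configurable.
* Scores are computed on FPKM ranks directly — ranks are invariant to any
  strictly monotone transform, so a log transform would change nothing.
* Genes missing from the matrix are dropped per set; a set falling below
  `min_set_genes` (default 3) is dropped with a warning, never silently.
* Average ranks for ties keep the statistic deterministic and
  gene-order-independent.

Scores are min–max normalized **per set** across the cohort before
clustering (a whole-matrix variant is available via `scheme="global"`; which
scheme a given study used is often unstated, and per-set is this package's
default because it gives every cell type equal leverage in cluster space).
Composite scores are plain sums of normalized rows: protumor = MDSC +
regulatory T + neutrophil + M2 macrophage; antitumor = activated CD4 T +
activated CD8 T + activated B + NK + M1 macrophage.

## Subtype discovery and replication

Clustering runs on the samples in normalized score space with Euclidean
distance (the rows are already in [0, 1]; no further z-scoring).

* **K selection**: full-data K-means (fixed seed) per K; average silhouette,
  Calinski–Harabasz and Dunn vote for their maximum, Davies–Bouldin for its
  minimum; modal vote wins, ties break toward the smallest K. Four
  well-defined indices keep the vote implementable and testable; large index
  batteries add little beyond these four families (compactness, variance
  ratio, cluster overlap, separation/diameter).
* **Stabilized K-means**: a reference K-means (k-means++, 10 restarts) fixes
  label semantics; each of 1000 iterations fits K-means to a fresh 80%
  subsample, and its centroids are matched to the reference by
  minimum-total-distance Hungarian assignment. Refined centroids are the
  element-wise mean of the matched centroids (medoid refinement available via
  `refine="medoid"`). Final labels are nearest-refined-centroid; iterations
  producing an empty cluster are re-drawn, and more than 10% re-draws abort.
* **Naming rule**: clusters are ordered by mean total normalized
  infiltration; for K = 3 the names follow the cold/intermediate/inflamed
  convention C2 < C1 < C3.
* **Transfer and IGP**: an external cohort scored and normalized the same way
  is labeled by nearest centroid. After Hungarian label alignment, the
  in-group proportion of a de-novo cluster k is the percentage of its
  samples whose transferred label is also k. This is the centroid-prediction
  form of IGP; the original nearest-*neighbor* IGP variant is a different
  statistic and is not implemented.

## Characterization

* **Differential expression**: one-vs-rest two-sided rank-sum test per gene
  on FPKM, log2FC = log2((mean_in + 1)/(mean_out + 1)), BH adjustment over
  all genes; differential ⇔ |log2FC| > 1 AND FDR < 0.05 AND adjusted
  p < 0.001 (all strict). A negative-binomial count model is deliberately not
  used: the three thresholds, not the test engine, define the gene sets the
  rest of the pipeline consumes, and FPKM matrices carry no count
  information. Constant genes are recorded with p = 1, not dropped.
* **ORA**: upper-tail hypergeometric probability of the observed overlap
  between differential genes and a user-supplied GMT set; no annotation
  databases are downloaded.
* **Categorical association**: Pearson chi-square without continuity
  correction.
* **Survival**: product-limit (KM) curves per group and the k-group log-rank
  chi-square with k − 1 df (via lifelines); groups with no events contribute
  expectations only. Multiple pairwise comparisons use rank tests with BH
  rather than exact Dunnett quantiles.

## Radiomic features

851 features per MR sequence: 14 shape + 18 first-order + 75 texture on the
original image, and 18 + 75 on each of 8 single-level stationary Haar
subbands. Conventions:

* **Discretization**: fixed bin count (32 equal-width bins over the in-mask
  range) per image/subband. A fixed count keeps level structure comparable
  across samples regardless of intensity scale; fixed bin width is the
  natural alternative when absolute units are meaningful. Note equal-width
  binning is *not* invariant to monotone intensity transforms.
* **GLCM/GLRLM**: symmetric matrices, distance 1, the 13 unique 3D
  directions, features computed per direction then averaged.
* **GLSZM/GLDM/NGTDM**: 26-connectivity. GLDM uses α = 0 (equal level) and a
  dependence size of 1 + the number of dependent neighbors, so the smallest
  dependence is 1 and the small-dependence emphases are always defined.
* **Shape**: mesh area/volume from a marching-cubes surface of the mask. The
  mask is lightly Gaussian-smoothed (σ = 0.8 voxels) before triangulation;
  a binary surface is a staircase that overestimates area by ~8% and pulls a
  sphere's sphericity to ~0.92, while the smoothed surface restores it to
  within 1% of the analytic value. Masks too small for the smoothed level
  set fall back to the binary mesh. Axis lengths are 4·√eigenvalue of the
  physical-coordinate covariance; degenerate (flat) axes fall back to the
  within-voxel uniform variance so Elongation/Flatness stay in (0, 1].
* **Wavelet**: undecimated Haar, periodic boundary, implemented as axis-wise
  separable filtering; it agrees with `pywt.swtn` exactly up to pywt's
  one-voxel grid shift and detail-filter sign convention (verified in the
  test suite). Subbands are named by per-axis L/H letters in x, y, z order.
* **Intensity normalization**: a per-volume z-score is available
  (`normalize=True`) but **off by default**. Histogram-style normalization
  needs a reference cohort; a per-volume z-score, meanwhile, removes every
  affine scanner effect by construction, which would leave the downstream
  harmonization stage with nothing to correct — in this pipeline scanner
  effects are the explicit responsibility of ComBat, and raw intensities let
  them reach the first-order features.
* Feature extraction crops to the mask bounding box plus a 4-voxel margin
  (the wavelet filters see real context); any non-finite feature aborts with
  the feature's name.

Preprocessing intentionally excluded: bias-field correction, inter-sequence
registration and histogram matching (synthetic volumes are generated
pre-aligned; real inputs are expected already preprocessed).

## Feature quality

* **ICC(2,1)** — two-way random effects, absolute agreement, single
  measure — per feature on subjects × 2 delineations:
  (MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E)). The filter
  requires both the intra-rater and inter-rater ICC ≥ 0.85. ICC(3,1) is a
  flag away. Zero-total-variance features report ICC 1 with a warning. Note
  the null sampling SD of ICC with two raters is ≈ 1/√n/√2 — at n = 50
  repeatability subjects, pure-noise features scatter ±0.14, which the 0.85
  threshold comfortably absorbs. The filter runs on raw features; ComBat
  runs after it (ICC should judge the features as extracted, and
  harmonization parameters should be fitted only to features that survive).
* **ComBat** — parametric empirical-Bayes location/scale harmonization:
  standardize per feature by design-based grand mean and pooled residual
  variance; estimate per-batch locations γ and scales δ²; shrink via
  normal / inverse-gamma priors with moment-matched hyperparameters,
  iterating the conditional posteriors to 1e-6; back-transform. It matches
  Bioconductor's `sva::ComBat` to the iteration tolerance (cross-checked in
  the tests), with two documented conventions of this implementation: each
  feature's grand mean is restored exactly after adjustment, and features
  with a zero-variance batch get a location-only adjustment. No biological
  covariates are protected, because subtype labels are unknown at
  harmonization time in the intended workflow. Two properties of EB
  shrinkage worth knowing: (1) re-running ComBat on harmonized data is not a
  strict no-op — the scale posterior pulls per-feature variances toward the
  prior mean, so a second pass moves values by O(1/√n) SD (it is a strong
  contraction, tested as such); (2) when every feature carries an *identical*
  batch offset, the prior variance of γ is pure estimation noise and the
  location estimates over-shrink — realistic scanner effects vary by
  feature, and then batch means equalize almost exactly.

## Signature

Screening routes each feature to one-way ANOVA only when every group passes
Shapiro–Wilk and the groups pass Levene's test (α = 0.05 each), else
Kruskal–Wallis; features with raw p < 0.05 survive. The raw-p screen is a
deliberately liberal filter (no multiplicity correction) — the forest
re-ranks the survivors anyway. A 100-tree random forest ranks survivors by
mean impurity decrease (permutation importance available by flag); the top
10 (ties broken by name) are retrained as the signature. Selection sees only
the training table — the evaluation interface takes a disjoint cohort.
Evaluation: accuracy; per-class one-vs-rest trapezoidal AUC,
macro-averaged, with a stratified-bootstrap percentile 95% CI (2000
resamples); per-class and macro sensitivity, specificity, F1; ROC and PR
curve points. An absent test class leaves its AUC undefined and the macro
average runs over the defined classes with a warning.

## Radiogenomic linkage

Pearson r with two-sided t-distribution p-values per (signature feature,
enrichment score) pair over the shared samples; BH adjustment is applied
once over the entire feature × score grid (per-feature scope available), and
adjusted p < 0.05 is significant. Constant variables yield undefined r and
are excluded from the adjustment. Replication requires significance in both
cohorts with the same sign of r. Under a no-coupling null the expected
replicated fraction behaves like the product of the two per-cohort error
rates (≪ α), which the tests verify by simulation.

## Synthetic cohorts

The generator reproduces the structure the analysis assumes; its defaults
are the study conditions.

* **Panel**: 29 cell types totalling 803 disjoint synthetic marker genes
  (sizes 27–28 — the true per-type marker counts are not public, so equal
  split is an emulation, not a reconstruction), nine of them carrying the
  composite-score roles; 1200 background genes, six 30-gene pathway sets.
* **Archetypes**: per-sample base infiltration ~ Beta with subtype means
  0.15 (C2), 0.45 (C1), 0.8 (C3) and concentration 60; per-cell-type jitter
  SD 0.05; protumor types +0.15 in C3; antitumor types +0.12 in C1. The
  concentration and the C1 compositional skew encode that the three
  subtypes are *distinct states*, not points on a single infiltration
  gradient — C1 is a lymphocyte-active transition state, and without a
  compositional identity of its own, no internal index battery would ever
  prefer K = 3 over a 1-D gradient split.
* **Expression**: log2(FPKM+1) = per-gene baseline N(5, 2) + N(0, 0.5) noise
  + 3.0 log2-units × infiltration on marker genes + 1.5 log2-units ×
  activity on pathway genes (hypoxia, angiogenesis, ECM remodeling, antigen
  presentation, leukocyte adhesion up in C3 and half-way in C1; calcium
  signaling up in C2 and 0.7× in C1); FPKM = 2^x − 1. Log-normal noise
  suits the rank-based scoring; a count model would add machinery the
  pipeline never exploits. Marker shifts of ~3 log2-units between absent
  and abundant infiltration are in line with what cell-type markers do in
  bulk tissue.
* **Images**: default 32³ voxels at 1 mm (the smallest grid with full
  texture/wavelet support — it keeps whole-cohort extraction desk-scale;
  feature counts are size-invariant). Ellipsoidal tumors (radius 5–8
  voxels scaled with the grid) whose mean intensity, 2-voxel rim contrast,
  Gaussian-filtered texture correlation length (σ = 2.0 / 1.2 / 0.7 for
  C2/C1/C3) and axis eccentricity depend on subtype; additive N(0, 3) noise;
  per-(batch, channel) gain N(1, 0.1) and offset N(0, 5). Rater masks are
  the truth dilated or eroded by ≤ `rater_perturb_radius` with 5% random
  boundary flips; radius 0 reproduces the truth exactly.
* **Survival**: exponential with per-subtype hazards 1/35.3, 1/45.6,
  1/25.7 months⁻¹ (C1/C2/C3 — cold longest, inflamed shortest), censoring
  probability 0.2 with uniform censoring times.
* **Determinism**: one master seed; every stage draws from a spawned
  substream, so identical configs are bit-identical.

What passing on these cohorts does **not** show: robustness to unmodeled MR
physics (bias fields, misregistration, non-affine scanner effects), to
marker panels whose sets overlap or mismatch the transcriptome, to
non-exponential survival, or to archetype structure weaker than the
configured effect sizes. The generator's no-signal configurations
(effects = 0) are used to verify the negative controls: chance-level
clustering, null signature AUC, and no replicated linkage pairs.

## Numerical conventions

* Ranks: average for ties everywhere.
* K-means: k-means++ with 10 restarts for reference/selection runs, 1 restart
  inside subsample iterations.
* BH: statsmodels step-up; NaN inputs are rejected, not propagated.
* Bootstrap CIs: stratified percentile, 2000 resamples.
* First-order Skewness/Kurtosis of a constant region are defined as 0;
  GLCM Correlation and MCC of a single-level region are defined as 1.
* All analysis-level randomness (subsampling, forests, bootstraps) derives
  from explicit integer seeds; the pipeline orchestrator spawns per-stage
  seeds from one master seed.

## Problem sizes

The test suite and the acceptance script run the full workflow at the
three-cohort design sizes (210 expression-only discovery samples; 130
training and 55 validation samples with imaging; 50 repeatability subjects
with three delineations each), with 32³ volumes as above; calibration
experiments use 1000 null replicates. These sizes exercise every code path
at the study's sample counts while remaining single-CPU-friendly.
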