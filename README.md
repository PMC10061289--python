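# gliomune

Glioma immune subtyping from bulk RNA-seq, and noninvasive prediction of the
subtypes from multiparametric MRI.

Adult diffuse gliomas differ sharply in their tumor microenvironment: some are
"inflamed" (heavy infiltration by both pro- and antitumor immune cells), some
are immunologically "cold", and many sit in between. The subtype matters for
immunotherapy, but RNA sequencing requires resected tissue. `gliomune`
implements the full radiogenomic workflow that (1) discovers immune subtypes
from expression data, (2) predicts them from preoperative MRI, and (3) links
the predictive imaging features back to biology:

1. **TME scoring.** A brain-specific marker panel (29 immune cell types, 803
   marker genes, including microglia) is scored per sample with the ssGSEA
   rank-weighted running sum,
   `ES(G, j) = Σ_i [P_in(i) − P_out(i)]` with `P_in(i) = Σ_{k≤i, g_k∈G}
   ρ_k^α / Σ_{g∈G} ρ^α` (α = 0.25). Scores are min–max normalized per cell
   type; composite protumor (MDSC + Treg + neutrophil + M2) and antitumor
   (activated CD4/CD8 T + activated B + NK + M1) scores summarize each sample.
2. **Subtype discovery.** Stabilized K-means: 1000 subsampled (80%) K-means
   runs are Hungarian-matched to a full-data reference and their centroids
   averaged; K is chosen by a majority vote of silhouette, Calinski–Harabasz,
   Davies–Bouldin and Dunn indices. Subtypes are named by infiltration:
   C2 (cold) < C1 (intermediate) < C3 (inflamed). The centroids transfer to
   external cohorts, and replication is measured per cluster with the
   in-group proportion (IGP).
3. **Radiomics.** From each of 4 MR sequences (T1, T2, FLAIR, T1c) and the
   tumor mask: 14 shape + 18 first-order + 75 texture features (GLCM, GLRLM,
   GLSZM, NGTDM, GLDM; IBSI-style definitions) on the original image, plus
   first-order + texture on 8 stationary Haar subbands — 851 features per
   sequence, 3404 per patient.
4. **Feature QC.** Features with intra- or inter-rater ICC(2,1) < 0.85
   (computed against repeat/rater-perturbed delineations) are discarded;
   scanner effects are removed with parametric empirical-Bayes ComBat.
5. **Signature.** Per-feature ANOVA/Kruskal–Wallis screen (routed by
   Shapiro–Wilk + Levene, p < 0.05), importance ranking by a 100-tree random
   forest, retraining on the top 10 features, and evaluation by accuracy,
   macro one-vs-rest AUC (bootstrap CI), sensitivity, specificity and F1.
6. **Radiogenomic linkage.** Pearson correlation of the 10 signature features
   with pathway/cell-type enrichment scores, BH-adjusted over the whole grid;
   pairs significant in both cohorts with consistent sign count as
   replicated.

A synthetic cohort generator (`gliomune.synthetic`) produces paired
expression, imaging and survival data with the statistical structure the
analysis assumes (three infiltration archetypes, subtype-linked pathway
activity, subtype-dependent tumor appearance, scanner batch effects,
rater-perturbed masks, subtype-dependent survival), so the entire pipeline is
testable end to end without patient data.

## Worked example

```python
from gliomune import (
    CohortConfig, make_cohort, ssgsea_scores, minmax_normalize,
    select_k, stabilized_kmeans, assign_nearest_centroid, compute_igp,
    align_labels,
)

discovery = make_cohort(CohortConfig(n_samples=210, with_images=False, seed=0))
scores = minmax_normalize(ssgsea_scores(discovery.expression, discovery.panel))
k, report = select_k(scores, seed=0)
print("chosen K:", k, "votes:", report.votes)

model, labels = stabilized_kmeans(scores, k, n_iterations=1000, seed=0)
print(labels.value_counts().to_dict())

external = make_cohort(CohortConfig(n_samples=130, with_images=False, seed=1))
ext_scores = minmax_normalize(ssgsea_scores(external.expression, external.panel))
transferred, _ = assign_nearest_centroid(model, ext_scores)
_, denovo = stabilized_kmeans(ext_scores, k, n_iterations=1000, seed=2)
aligned, _, _ = align_labels(transferred, denovo)
print("IGP (%):", compute_igp(aligned, transferred))
```

prints

```
chosen K: 3 votes: {'silhouette': 3, 'calinski_harabasz': 3, 'davies_bouldin': 2, 'dunn': 3}
{'C1': 90, 'C3': 61, 'C2': 59}
IGP (%): {'C1': 100.0, 'C2': 100.0, 'C3': 100.0}
```

i.e. three of the four internal indices vote for three subtypes, the cluster
sizes track the configured archetype proportions (94/55/61 expected at
n = 210), and the centroid-transferred subtypes replicate perfectly per
cluster in an independently generated cohort.

The same stages are scriptable from the shell (`gliomune simulate | score |
subtype | transfer | characterize | radiomics | qc | signature | linkage |
run`); `gliomune run --out DIR --seed 0` executes the whole workflow and
writes a report bundle.

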