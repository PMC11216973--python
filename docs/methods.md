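# Methods

## Problem and model

Imaging cohorts accumulate *batch effects* (BEs): systematic technical
variation from scanners, sites, staining runs or acquisition protocols that
is unrelated to biology. When a model's training and test sets differ in
their technical composition, evaluation is biased — optimistically when a
site signature leaks the label, pessimistically when a whole presentation is
held out. `cohortsplit` detects batch structure directly from per-image
quality-control (QC) metrics (as emitted by WSI or MRI QC tools) and builds
patient-level partitions that either balance that structure (best case),
ignore it (average case, the field's default), or maximize it (worst case,
for stress-testing).

The pipeline:

1. **Ingest.** One TSV row per image: identifier column first, numeric QC
   metrics after. Lines starting with `#` are preamble; undeclared
   non-numeric columns are excluded and logged. Missing or non-finite metric
   values are imputed with the column median over finite entries; a column
   more than 50% missing is dropped. Patient ids derive from image ids by a
   regex capture or delimiter split (identity if none: one image per
   patient, the MRI case).
2. **Patient features.** Image rows are reduced to one vector per patient —
   arithmetic mean by default, median as an option — then z-scored per
   metric (sample sd, ddof=1). Scaling matters because QC metrics span
   wildly different units; the fitted center/scale are stored so held-out
   patients transform identically. Zero-variance metrics are dropped with a
   warning.
3. **Embedding.** UMAP to 2-D (defaults: 15 neighbors, min_dist 0.1,
   Euclidean, fixed seed). UMAP is used because a fitted manifold can embed
   new patients without refitting. Rows are canonicalized (sorted by patient
   id) before the fit and mapped back, making the embedding independent of
   input row order — UMAP itself is not permutation-equivariant even with a
   fixed seed. Cohorts smaller than the neighbor count shrink it to n−1 with
   a warning; fewer than 3 patients is an error.
4. **BE groups.** k-means in the 2-D embedding, replicated (default 10
   runs on nested derived seeds, lowest within-cluster sum of squares wins),
   labels renumbered by first-patient appearance so results are seed-stable.
   The default cluster count is `k = ceil(n_patients / fold_count)` — with
   3-fold CV this makes roughly 3-patient clusters so each fold can take one
   member per cluster (91 patients → k = 31). Three internal validity
   indices summarize batch-effect severity: silhouette, Calinski–Harabasz,
   Davies–Bouldin.
5. **Partitioning** (always patient-level; images inherit their patient's
   assignment):
   - *best case, ratio mode*: test slots are apportioned to BE groups by
     largest remainder (Hamilton) on quota `ratio·|g|`, ties on the
     fractional part broken by ascending group index, each group capped at
     `min(ceil(quota), |g|−1)` so no group is emptied of training patients;
     singleton groups go to training with a warning. Test members are drawn
     uniformly within each group.
   - *best case, fold mode*: each group's members are shuffled and dealt
     over the folds ordered by ascending (current size, fold index). Dealing
     extras to the currently smallest folds provably keeps overall fold
     sizes within one of each other.
   - *average case*: uniform random assignment, half-up rounding of
     `ratio·n` in ratio mode, round-robin after a shuffle in fold mode.
   - *worst case* (fold mode only): k-means with k = n_folds, then greedy
     balancing — while group sizes are uneven, the largest group's member
     nearest the smallest group's centroid moves there, centroids recomputed
     after each move. Balanced groups become folds verbatim (91 patients →
     31/30/30). A degenerate embedding (all points identical) falls back to
     an arbitrary balanced split with a warning.
6. **Batch-effect test.** A random forest predicts a per-patient categorical
   label (site, scanner) from the standardized patient features; the
   statistic is mean stratified k-fold CV accuracy (default 5 folds, 100
   trees). B permuted-label replicates (default 999) recompute the identical
   statistic; `p = (1 + #{null ≥ observed}) / (B + 1)` (add-one, never
   exactly zero). Metric importances come from a forest refit on all
   patients with true labels, normalized to sum to one. The test runs at
   patient level to avoid pseudoreplication from multi-image patients. The
   forest is implemented as explicit bagging over sklearn decision trees
   (bootstrap per tree, sqrt feature subsets, majority vote with ties to the
   lowest class index); this is the textbook random forest with much lower
   per-fit overhead than the ensemble wrapper, which matters when the
   permutation studies below fit ~50k tiny forests. A test cross-checks it
   against `RandomForestClassifier`.
7. **Reports.** Per-patient results CSV (metric values used, UMAP x/y,
   BE-group index, assignment, the three severity metrics; floats at full
   round-trip precision), an embedding scatter ("v" = train, "o" = test,
   color = BE group), a contact sheet of per-group representative thumbnails
   (nearest-to-centroid patients), and a timestamped run log that captures
   every warning.

All randomness flows from one user seed through named derivations
(`derive_seed(seed, stage, index)`, crc32-based, < 2^31), so each stage is
independently reproducible and replicate sequences nest.

## Synthetic cohorts

The generator plants the batch structure the pipeline is meant to find:
patients are split evenly over `n_batches`; batch centers are random
orthonormal directions scaled so every pair of centers is exactly
`separation` apart in units of the within-batch sd (isotropic unit Gaussian
per patient); each image adds N(0, 0.1²) jitter around its patient's latent
vector. `label_confounding` is the probability a patient's site label equals
its batch (otherwise uniform over the other batches), so `1/n_batches` gives
labels independent of metrics — the null — and 1.0 makes site a perfect
batch proxy. Defaults (30 patients, 3 images/patient, 6 metrics, 3 batches,
separation 4) describe a small single-study cohort with a clearly present
but not trivial batch effect.

The generator does **not** emulate heavy-tailed metric distributions,
correlated metrics, site-specific missingness, or unbalanced batch sizes;
tests built on it validate the pipeline's logic and statistics, not
robustness to those artifacts.

## Evaluation experiments (`cohortsplit.experiments`)

Problem sizes are chosen to run on one CPU in minutes.

- **Cluster recovery**: 20 cohorts of 60 patients, 3 blobs at 6 sd, full
  standardize→UMAP→replicated-k-means path, scored by adjusted Rand index
  against the planted batches. 60 patients keeps each blob (20) larger than
  the default UMAP neighborhood (15); when blobs are smaller than the
  neighborhood the k-NN graph bridges them and recovery degrades — a real
  property of neighborhood embeddings worth knowing when setting
  `n_neighbors` on small cohorts.
- **Type-I calibration**: 200 null cohorts (separation 0, confounding 1/3),
  B = 199, α = 0.05. The permutation test is valid by construction for any
  forest size, so the Monte-Carlo studies use a 5-tree forest with 3-fold
  CV to keep ~50k statistic evaluations tractable; ties in the discrete
  accuracy statistic make the add-one p-value mildly conservative (observed
  rate ≈ 0.03–0.05). A cohort whose random site classes are too small for
  CV is redrawn — independent of the metric–label relation under the null.
- **Power**: 50 cohorts at separation 3 with site = batch; same test
  settings.
- **Partition spectrum**: 30 cohorts (30 patients, separation 6, confounding
  0.9); a nearest-class-centroid classifier is scored across 3-fold plans
  built best/average/worst-case. The classifier treats a test class absent
  from training as an error — exactly the failure batch-aligned folds
  create. Conditions were fixed after a design pilot: at separation 3 the
  best-vs-average gap drowns in noise, at separation 6 it is reliably
  resolvable with 30 paired cohorts. Expected ordering: best ≥ average ≫
  worst.

## Numerical choices and edge cases

- Ratio rounding is half-up (`floor(x + 0.5)`), never banker's, for
  cross-platform determinism.
- k-means replicates that return an empty cluster are re-seeded up to 10
  times, then error.
- Severity metrics for a single group (or k = n) are NaN sentinels with a
  warning, not exceptions.
- The worst-case balancer also moves members when `max − min > 1` even if no
  group exceeds `ceil(n/k)`, otherwise 31/31/29 could survive for n = 91.
- CSV floats are written with `repr` and read back with exact parsing
  (pandas' fast parser is off by 1 ulp), so a written results file
  reproduces values bit-equal.
- Identifier comparisons are case-sensitive exact string matches.

## Known limitations

- Clustering is patient-level only; an image-level mode is deliberately not
  provided (multi-image patients are averaged).
- One TSV per run; merging multiple QC runs is left to the user.
- UMAP coordinates are reproducible for a fixed seed on a fixed platform,
  not across BLAS/numba versions.
- The worst-case construction is pinned only by its balance guarantee; other
  balanced batch-maximizing splits exist.
- The BE test detects association between QC metrics and a label; it does
  not correct or remove batch effects.
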