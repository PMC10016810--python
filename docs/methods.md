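# Methods

## The problem and the model

After a stroke in the middle-cerebral-artery territory, upper-limb motor
function (measured by the upper-extremity Fugl–Meyer Assessment, FMA,
0–66 points) recovers to very different degrees across patients. The
analysis implemented here predicts the **FMA recovery score**

    recovery% = 100 · (FMA_3m − FMA_2w) / (66 − FMA_2w)

— the percentage of the maximal possible improvement actually achieved
between two weeks and three months — from features available shortly
after the stroke. The key idea is *virtual lesioning*: instead of
measuring the patient's own white-matter connectivity (which needs long
diffusion-MRI acquisitions), the patient's binary lesion mask is
intersected with streamline tractograms from healthy subjects. Every
streamline passing through a lesioned voxel is deleted; the surviving
streamlines are aggregated into a region-by-region connectome whose
graph properties quantify how much the lesion disrupts the whole
network, including regions far from the lesion (diaschisis).

## Pipeline

1. **Virtual lesioning.** For each patient and each healthy tractogram,
   delete every streamline whose rasterized path (supersampled at ≤ 0.5
   voxel; a conservative "passing through" test that does not miss
   fast-crossing segments) intersects the lesion mask.
2. **Connectome construction.** Each surviving streamline whose two
   endpoints map to distinct parcellation regions adds one count to that
   region pair; endpoints in background snap to the nearest labelled
   voxel within a Chebyshev radius of 2 (configurable). Edge weight
   (i, j) = count / (V_i + V_j), the streamline count normalized by the
   summed region voxel volumes. Self-pairs are excluded and the diagonal
   is zero: all measures assume simple graphs.
3. **Graph measures.** Eleven measures on binary graphs and seven on
   weighted graphs (Table below). Binary graphs come from density-matched
   thresholding: the weighted density d_w = Σ_{i<j}(w_ij/w_max)/(N(N−1)/2)
   sets the target edge density, and the k = round(d_w·N(N−1)/2)
   largest-weight edges are kept (ties broken lexicographically;
   zero-weight pairs never become edges). Node-level measures are
   summarized by mean and/or median; all values are finally averaged
   over the healthy connectomes, so each patient gets one 18-vector.
4. **Feature sets.** Five nested ladders: (1) age + initial FMA,
   (2) + lesion volume, (3) + CST asymmetry (the clinical benchmark),
   (4) + the connectivity battery, (5) = set 4 without CST asymmetry.
   CST asymmetry is Stinear's index (FA_H − FA_L)/(FA_H + FA_L) of the
   mean fractional anisotropy of the two cortico-spinal tracts; the FA
   means are inputs, not computed from images here.
5. **Prediction.** Nested leave-one-subject-out (LOO) ridge regression.
   Per outer fold: features are z-scored on the training patients only
   (population SD); for sets 4/5 the most collinear feature is dropped
   iteratively by variance inflation factor (VIF = 1/(1−R²) of each
   feature regressed on the others) until all VIFs ≤ threshold
   (default 23); the ridge penalty λ minimizes the inner LOO error over
   a 25-point logarithmic grid 10⁻³…10³; the fitted weights predict the
   held-out patient. The solver uses the stationarity system
   (ZᵀZ + NλI)β = Zᵀy with the intercept handled by target centring.
6. **Evaluation.** Accuracy is R² = 1 − Σ(Y−Y′)² / Σ(Y−mean(Y′))², with
   the denominator centred on the mean of the *predictions* (the
   conventional observed-mean variant is available behind a flag, never
   default). Patients are labelled fitters of the ~70% proportional
   recovery rule when recovery% > 30 (strict; 30 itself is a
   non-fitter), cross-checked by hierarchical clustering (below);
   classification of predicted labels is scored by specificity,
   sensitivity, PPV and NPV with fitter as the positive class and
   undefined ratios reported as missing, not zero. Uncertainty on R²
   comes from 10 000 subsamples of 32 predictions drawn without
   replacement (2.5/97.5 percentiles); univariate structure from
   Spearman correlations (Bonferroni-corrected over the number of
   features), rank-sum tests between fitters and non-fitters, and an
   average-linkage dendrogram on 1 − Spearman-ρ feature distances.

## Measure battery

Binary (on the density-matched graph): density, median degree,
mean/median Watts–Strogatz clustering coefficient, mean flow
coefficient, transitivity, Louvain modularity, mean/median eigenvector
centrality, mean/median unnormalized shortest-path betweenness.
Weighted: algebraic connectivity (second-smallest eigenvalue of the raw
Laplacian D − W, so it scales with the weights), mean/median eigenvector
centrality of W/w_max, weighted Louvain modularity, weighted global
efficiency (mean of 1/d(i,j) with edge lengths w_max/w_ij, unreachable
pairs contributing 0), mean participation coefficient
1 − Σ_m (s_im/s_i)² over Louvain modules, and quasi-idempotence (the
Pearson correlation between the node strengths of W/w_max and of its
square, indexing how strength structure survives two-step connectivity).

Conventions for degenerate cases, all tested: clustering/flow = 0 for
degree < 2; participation = 0 for isolated nodes; empty graph → density
0, node summaries 0, modularity 0; quasi-idempotence is missing (NaN)
when strengths have zero variance, and missing values are excluded
pairwise (with counts) in the per-patient average.

The flow coefficient follows the Brain-Connectivity-Toolbox convention:
the fraction of a node's neighbour pairs connected through it but not
directly — on undirected graphs the exact complement of the local
clustering coefficient. Louvain runs with 10 seeded restarts keeping the
best modularity, making modularity and participation deterministic
given the seed.

## Synthetic study

No patient data are distributed, so a synthetic module generates the
whole study at will. What it emulates, and what it does not:

* **Parcellation**: the two-hemisphere structure of a volumetric atlas
  (first half of the region IDs left, second half right) as contiguous
  boxes on a voxel grid — 36 regions on a 20³ grid by default (the real
  atlas has 360; the count is a size parameter, not a claim of
  anatomical realism). No cortical geometry, no subcortex.
* **Healthy tractograms**: one template of straight polylines whose
  region pairs are drawn by preferential attachment (probability ∝
  (endpoint count + 1)^hub_exponent, default exponent 1), so genuine
  hubs exist; each of the 60 subjects is the template plus Gaussian
  vertex jitter (SD 0.3 voxel). This preserves the semantics of
  averaging measures over healthy connectomes cheaply; it does not model
  real inter-subject anatomical variability or curved fasciculi.
* **Lesions**: ellipsoidal voxel blobs. For a fixed seed the centre and
  axis ratios are frozen and only the radius grows with severity, so
  lesion families are nested (severity 0 → empty; severity 1 is capped
  at ≥ 50% of brain voxels). Centres are biased towards the designated
  CST corridor (probability 0.5), a uniform brain voxel (0.25) or the
  highest-traversal-density hub voxel (0.25).
* **CST and FA**: per hemisphere, the region nearest the hemisphere
  centroid stands in for the cortico-spinal corridor; its streamlines
  are the CST bundle. The ipsilesional mean FA is attenuated
  proportionally to the fraction of CST streamlines the lesion
  transects: FA_L = FA₀·(1 − 0.5·fraction_hit), FA_H = FA₀ with
  FA₀ ~ U(0.5, 0.6) — producing the lesion-load/asymmetry coupling the
  benchmark feature relies on.
* **Cohort**: severity ~ U(0.05, 0.9); age ~ N(65, 12²) clipped to
  [28, 85] and deliberately carrying no planted effect (age is a null
  feature); initial FMA = 55·(1 − severity) + N(0, 3²), rounded and
  clipped to the [0, 55] inclusion range. True network damage d is the
  lesion-induced drop in mean weighted global efficiency, computed by
  actually running the virtual-lesioning machinery, never assumed.
  Recovery follows the planted model

      recovery% = clip(25 + 1.0·FMA_2w − 100·asymmetry − 60·d + ε, 0, 100),

  ε ~ N(0, noise_sd²) with noise_sd = 2 by default, and
  FMA_3m = round(FMA_2w + recovery/100·(66 − FMA_2w)). The coefficients
  were chosen so that the three planted drivers each move recovery by
  tens of percentage points over their realized ranges and the clip at 0
  produces a mass of barely-recovering patients — the fitter/non-fitter
  two-group structure of real cohorts. Because ε is the only stochastic
  term given the lesion, a pipeline that reconstructs the drivers can
  approach R² = 1 − var(ε)/var(recovery); the acceptance bound of 0.8
  leaves room for the clip nonlinearity and FMA rounding.

Passing tests on this phantom demonstrate that the machinery recovers
planted effects under its own assumptions (linear recovery model, focal
ellipsoidal lesions, jitter-only inter-subject variability). They say
nothing about anatomical realism, about how informative these measures
are for real patients, or about the reported effect sizes in any real
cohort.

## Numerical and design choices

* **Weighted density** is undefined in common usage for this purpose;
  the max-normalized mean weight is used because it reduces to binary
  density on 0/1 matrices and lands in (0, 1) where a thresholding
  target is usable.
* **Eigenvector centrality** is the principal eigenvector (unit norm,
  nonnegative). If the top eigenvalue is degenerate (identical
  disconnected components), the all-ones vector is projected onto the
  top eigenspace, which is a nonnegative representative.
* **Inner λ search** refits honestly for every inner fold and grid
  point; ties go to the smallest λ.
* **VIF selection pool**: connectivity measures and lesion volume are
  eliminable; age, initial FMA and CST asymmetry are protected. Ties at
  the maximal VIF drop the latest-added column, so selection traces are
  reproducible. If only protected features remain above threshold, the
  protected set is returned with a warning.
* **VIF operating threshold** (default 23) is a configuration value.
  The threshold sweep is exposed as a diagnostic curve; the pipeline
  never picks its own threshold from the outer accuracy curve, which
  would leak test information into model selection.
* **Fitter clustering**: patients are clustered (average linkage,
  Euclidean) in the plane of expected recovery 0.7·(66 − FMA_2w) versus
  actual recovery FMA_3m − FMA_2w. Both axes are FMA points, so the
  coordinates are standardized by one common scale (the SD of all
  centred coordinates); per-axis z-scoring would inflate whichever axis
  happens to vary least and destroy the separation the labelling relies
  on. Spearman distance between 2-D points is degenerate (any two
  distinct points correlate ±1) and is not offered. The clustering
  labelling is validated only by its agreement with the 30% threshold
  rule on separated cohorts.
* **Rank-sum test**: exact enumeration of all group assignments for
  pooled n ≤ 12 (tie-safe), tie-corrected normal approximation above;
  the standardized z is always reported alongside U (the count of pairs
  where the second group exceeds the first, ties half-weighted).
* **Bootstrap subsampling** is without replacement (a with-replacement
  flag exists), matching a subsample size smaller than the cohort.
* **Degenerate folds** (zero-variance target, all-constant features)
  raise errors rather than passing silently; constant training columns
  are dropped per fold with a warning.

## Problem sizes

The shipped study runs at 36 regions / 60 healthy tractograms of 5000
streamlines / 40 patients on a 20³ grid — the full cohort-level
pipeline (2400 virtually lesioned connectomes with the complete measure
battery, five nested-LOO prediction runs, a 20-permutation null and a
10 000-draw bootstrap) completes in a few minutes on one CPU. The unit
tests use a 16³ / 12-region / 6-subject phantom. Measure-level oracle
checks run exhaustively over all connected graphs with at most 6 nodes.

## Known limitations

* The phantom's streamlines are straight and its parcels are boxes;
  geometric effects (curvature, partial-volume, registration error) are
  out of scope, as are tractography and lesion segmentation themselves.
* With ~22 features and 39 training rows per fold, VIF's auxiliary
  regressions are exact OLS, but with fewer rows than features they fall
  back to a ridge-stabilized R² (penalty 1e-8).
* The binary betweenness median is frequently 0 at realistic densities,
  making that column constant across patients; the per-fold
  standardization then drops it with a warning — expected behaviour,
  not a defect.
* Louvain is a heuristic; with 10 restarts the partitions are stable on
  36-node graphs, but modularity-dependent measures carry a small
  partition-noise floor on near-degenerate graphs (tolerated explicitly
  in the permutation-invariance test).
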