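# Methods

This note documents the models, conventions and numerical choices behind
`canopyn`, and what the synthetic scenes do and do not establish about real
imagery.

## The analysis in one paragraph

Foliar nitrogen (% dry matter) is the dominant nutritional axis of eucalypt
browse for arboreal folivores; 1% N DM is the conventional favorability
threshold. The pipeline predicts per-tree canopy N from 19 multispectral
variables (5 reflectance bands + 14 indices) with a random forest, converts
the same features into a per-pixel probability of favorable foliage with a
binomial random forest, maps that probability over a 4-ha home range with
non-canopy masked out by the CHM, and finally asks whether plot-level mean N
predicts where gliders were detected, using a binomial GLM.

## Spectral features

The 19-variable stack comprises the five sensor bands and 14 indices held in
a registry (`canopyn.indices.INDEX_REGISTRY`). Five of them — GDVI
(NIR − Green), NDI Blue/NIR, NDI RedEdge/NIR, RI (Redness Index), VARI — are
the ones the nitrogen model typically retains; the other nine (NDVI, GNDVI,
NDRE, SR, GRVI, EVI, CIgreen, CIrededge, SAVI with L = 0.5) are standard
multispectral plant-chemistry indices chosen to cover the same band space.
The modelling protocol, not any specific extra-index list, is the
reproducible object; the registry is replaceable. Division-by-zero pixels
become NaN ("missing") and are excluded from any averaging, mirroring
masked-raster semantics. Note that GDVI is implemented as the plain
difference NIR − Green as printed in the source table, although the index
family published under that name elsewhere is parameterized differently;
the discrepancy is documented, not resolved.

## Canopy structure

* **CHM gridding** splats each height point as a disk (default radius 0.5 m)
  and takes the per-cell maximum — the sub-circle pit-closing approach for
  photogrammetric point clouds. Cells no disk reaches are ground (0 m).
* **Tree detection** is a variable-window local-maximum filter: the window
  width at a cell is the crown width predicted from the tree-height
  allometry fitted to field measurements (OLS, floored at 1 m, window
  clamped to ≥ 3 cells). Equal-height plateaus are merged and the plateau
  centroid becomes the marker — deterministic and orientation-independent.
* **Crown segmentation** is marker-controlled watershed on the inverted CHM,
  masked below the minimum canopy height, with 4-neighbour connectivity —
  the same rook adjacency used by the clumpiness metric, keeping one
  convention package-wide. Manual crown correction is replaced by an API
  hook (`apply_crown_overrides`) accepting externally supplied polygons.
* The CHM is resampled to the feature grid by nearest neighbour when
  resolutions differ (the survey's CHM was 0.5 m against ~2.5 cm imagery;
  how the original grids were co-registered is not stated).

## Per-tree spectra

Crown pixels are those whose centers fall inside the crown polygon and pass
the NDVI foliage mask (per-tree threshold, global default 0.6). Up to 1000
pixels per tree are drawn without replacement; each tree is summarized as
the arithmetic mean of each feature over its pixels — the mean of per-pixel
index values, not the index of mean reflectances, matching the extraction
order of the field protocol. Pixels with any missing feature are dropped
before subsampling so every row is a complete 19-vector. When a crown has
fewer than 1000 unmasked pixels, all of them are used.

## Nitrogen model

`NitrogenForestRegressor` is an sklearn-style estimator running the full
protocol in `fit`:

1. **Correlation pruning** (|Pearson r| ≥ 0.8): iteratively drop the member
   of the worst pair with the larger mean absolute correlation (the caret
   `findCorrelation` heuristic); constant features drop first with a
   warning.
2. **Forest fit** with `mtry = ceil(p/3)` (regression default) and 500 trees;
   optionally the tree count minimizing out-of-bag MSE over
   {100, …, 1000}, falling back to 500 when the curve is flat (< 1%
   relative range).
3. **Variable selection**: permutation importance is %IncMSE — the percent
   rise in out-of-bag MSE when a feature is permuted within each tree's
   out-of-bag rows, averaged over trees (the classical random-forest
   definition; scikit-learn's training-set permutation importance is not
   OOB-based, so this is computed directly from `estimators_samples_`).
   Features below 5 %IncMSE are dropped and the forest refit.

**Evaluation protocol** (`evaluate_repeated`): each of 100 repeats draws a
stratified 70/30 partition (response ranked into 5 quantile bins, 70%
sampled per bin — 150 trees give exactly 105/45), fits the estimator on the
training split, and reports "cross-validation" metrics as out-of-bag
predictions on the training rows and "independent validation" on the
held-out 30%. The protocol being reproduced contrasts cross- and
independent validation without naming folds; out-of-bag error is the
forest-native equivalent and is the documented interpretation here.
Aggregates are mean, median, SD, SE = SD/√n_repeats and CV per metric;
repeat seeds are `base_seed + repeat index`. The best repeat by
cross-validation R² (and by RMSE) is recorded; the best-R² model is the one
used for plot-level outputs. Visual outlier screening is replaced by a
reproducible rule (`drop_outliers`): remove observations with
|externally studentized residual| > 4 from a preliminary OLS fit; it is an
explicit optional step, not silently applied.

The digestible-N (digN) path runs identically but is explanatory only — no
predictive floor is asserted, matching the finding that multispectral
features in the 475–840 nm window do not transfer to digN.

## Habitat classification and mapping

Pixels inherit their tree's label (favorable iff tree N ≥ 1.0% DM, boundary
inclusive). The raw pixel pool is imbalanced (roughly 4:1); an equal-count
subsample (default 25,000 per class) is drawn before training, treating the
4:1 figure as the pre-subsampling prevalence. The classifier trains on 70%
of the balanced set; the operating threshold is the held-out score cutoff
maximizing TPR + TNR (the operational definition used for the published
threshold 0.49; Cohen's kappa at that threshold is reported as a separate
statistic). The split is at pixel level by default, mirroring the protocol
being reproduced; a grouped-by-tree split is available because pixel-level
splits leak tree identity (pixels of one tree are highly similar), making
pixel-level skill an optimistic estimate.

Maps: 4-ha square crops around plot centers, per-pixel probability from the
fitted forest, CHM masking below the field minimum sub-canopy height, then
favorable (p ≥ threshold) / unfavorable (p < threshold) / non-habitat
(masked). Mean/SD likelihood is computed over canopy pixels only (masking
precedes the statistic); class fractions use the full extent as denominator
so the three fractions sum to 100%.

**Clumpiness** follows the FRAGSTATS CLUMPY definition with rook
adjacencies, double-counted, no background exclusion: with G the class's
like-adjacency proportion and P its landscape proportion,
CLUMPY = (G − P)/(1 − P) when G ≥ P or P ≥ 0.5, else (G − P)/P; a class
filling the landscape is 1 by convention. The convention is pinned by an
exhaustive brute-force oracle in the tests. The headline per-plot value is
the favorable-class clumpiness; all three per-class values are retained.

**Bitterlich expansion**: a stem tallied by an angle gauge with constant
c (= 25 at basal-area factor 4) represents 10000/(π c² d²) trees per
hectare, d the DBH in metres.

## Detection ecology

Detection is binarized as glider count ≥ 1 (count models are out of scope).
The GLM is logistic regression fitted by Fisher scoring / IRLS to relative
tolerance 1e-8; standard errors come from the final weighted information
matrix, 95% CIs are Wald (estimate ± 1.96 SE). Published intervals for this
model are asymmetric (profile-likelihood style); Wald is the default here
and the reproduction target is the coefficients, not the intervals.
Complete separation is detected and flagged rather than silently returning
diverging estimates. Detection thresholds (minimum meanN, mean likelihood,
favorable fraction among detection plots) are reported as empirical minima,
not hard-coded constants.

On the bundled 30-plot survey table the fit converges in 6 iterations to
intercept −5.56 and slope 3.55 (reported to one decimal as −5.6 and 3.6),
matching an independent GLM implementation to 1e-6.

## Synthetic scenes

The generator emulates the study conditions: a square scene (default 200 m
= 4 ha, 0.25-m pixels so a scene is 800×800 rather than the survey's
0.025-m native resolution, which remains configurable), plots on a grid
across three elevation bands, five sampled dominant trees per plot plus
background trees, species N means spanning the observed 0.63–1.92% DM range
with low-N species in the lowlands. Trees sit on a jittered grid (one per
cell, jitter bounded by the cell), which guarantees non-overlapping crowns
and linear-time placement; crowns are paraboloid domes (base at half tree
height) so each tree has a single height maximum. Crown width follows a
linear allometry on height (slope 0.22 m/m, intercept 1 m, SD 0.4 m) so
the detector's window function is recoverable from the truth table.

Reflectance: green and NIR increase linearly with pixel-level N
(green = 0.03 + 0.05 N, NIR = 0.30 + 0.15 N; green reflectance relates to
N absorption features directly, and NIR − Green is the strongest known
multispectral N predictor), red-edge weakly (0.15 + 0.02 N), blue and red
flat. Three stochastic layers sit on top, each separately switchable:
per-pixel within-crown N scatter (SD 0.05% DM — within-crown variance is
not reported in the field data, so it is a parameter, not an asserted
value), a per-tree per-band offset (SD 0.02, representing crown-level
spectral individuality from structure/LAI/shadow — without it all
N-informative features are an exact rank-1 function of N and correlation
pruning would collapse them to a single predictor, which no real canopy
exhibits), and per-pixel sensor noise (SD 0.01). Ground/understory pixels
get high red and low NIR (NDVI ≈ 0.14, below the 0.6 mask) and heights
below the sub-canopy masking height (5 m). digN is simulated as N times a
per-species digestibility factor in [0.5, 1], with a configurable missing
fraction (default 0.2, mirroring 116/150 analyzable samples). Detections
are Bernoulli with logit −5.6 + 3.6·meanN, the published coefficients.

With all three stochastic layers at zero, per-tree mean green reflectance
inverts exactly to N — the recoverability invariant the tests assert.

**What passing tests show and do not show.** Synthetic scenes have a
monotone, noise-free-by-construction N–reflectance link, no shadows, no
BRDF or illumination gradients, no species-specific spectra, no
co-registration error and no crown overlap. Model skill on them (CV R²
≈ 0.67, TSS ≈ 0.77 under the default low-noise conditions) demonstrates
that the pipeline plumbing, selection logic and evaluation protocol are
correct and that the protocol recovers a signal it is pointed at — not that
real imagery carries that signal; the published real-data values (R² 0.69,
TSS 0.59) cannot be re-derived without the original imagery.

## Numerical conventions and degenerate inputs

* Missing raster values are NaN throughout; class rasters use uint8 codes
  1/0/255 (favorable/unfavorable/non-habitat).
* All randomness flows through `numpy.random.default_rng` seeds; scene
  generation uses stage-separated seed sequences so tree placement,
  rendering and detections are independently reproducible.
* Tie-breaks: plateau markers at the centroid cell; operating-threshold
  ties toward the lowest threshold; correlation-pruning ties drop the
  first-listed feature.
* Degenerate inputs fail loudly: empty pixel tables name the tree, all-equal
  heights reject the allometry, single-class training sets reject the
  classifier, separation flags the GLM, absent classes give NaN metrics
  with warnings.

## Problem sizes used in the checks

The test suite and examples run a 4-plot, 400-m scene with 200 trees at
0.25-m pixels, 20-repeat model evaluation with 100-tree forests, and
5000-per-class pixel subsamples — the full protocol at a desk scale chosen
so the whole suite completes in about a minute; all sizes scale up by
configuration (100 repeats, 500 trees, 25,000 per class are the defaults on
the estimator and protocol functions).

## Known limitations

* Pixel-level train/test splits overstate pixel-classifier skill (tree
  identity leaks between splits); use `groups` splitting for honest
  generalization to unseen trees.
* The watershed uses the CHM only; adjacent crowns of equal height merge
  when no valley separates them.
* GeoTIFF CRS tags are not written; georeferencing is a scene-local linear
  map embedded as JSON metadata.
* The %IncMSE computation scales with trees × features × OOB rows; for very
  large forests prefer fewer trees during selection.
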