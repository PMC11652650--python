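# Methods

## Scope and model

`habitatrf` implements a presence / pseudo-absence species distribution
model as a binary random-forest classifier over a harmonized stack of
environmental raster layers, with the Habitat Suitability Index (HSI)
of a cell defined as the fraction of trees voting "presence" and the
binary occupancy map as the majority vote (HSI ≥ 0.5). The workflow
assumes a single coordinate reference system for all inputs (no
reprojection), one presence label class, and predictors that are
meaningful as continuous per-cell values.

## Raster model and harmonization

A raster is a 2-D array plus an affine-style geotransform (top-left
origin, positive cell sizes) and a nodata sentinel. Cell (0, 0) is the
top-left cell; the centre of cell (i, j) is `origin + (j+0.5, i+0.5) ·
cellsize`; point-to-cell lookups use half-open intervals so edge points
belong to exactly one cell. Layers are stored as ESRI ASCII grids —
plain text, lossless at the printed precision, readable by any desktop
GIS — which keeps the whole artifact text-only.

Harmonization resamples every layer onto the grid of the coarsest
layer. The default is bilinear interpolation on the source cell-centre
lattice: target centres beyond the outermost source centres clamp to
the lattice edge, which makes the operator exact on affine surfaces,
the identity on the source's own grid, and free of overshoot
(output range ⊆ source range). Stencil corners that are nodata are
dropped and the remaining weights renormalized; a fully-nodata stencil
yields nodata. When coarsening by large factors, bilinear interpolation
is point sampling and discards sub-cell variance; a block-mean
aggregator is provided for that case, but bilinear remains the default
because it is the conventional choice for continuous fields.

Terrain derivatives use Horn's 8-neighbour stencil (the de-facto GIS
standard; no algorithm is canonical for this workflow otherwise). Edge
cells use replicated-edge values by default (`edge_policy="nodata"`
masks them instead); nodata neighbours fall back to the centre value.
Slope is reported in degrees [0, 90]; aspect in degrees [0, 360)
clockwise from north with flat cells set to nodata (no defined
direction) and exact north reported as 0, never 360; hillshade is the
standard illumination formula rounded to integers [0, 255], default sun
azimuth 315° and altitude 45°. On geographic (degree) grids the cell
size is converted to metres at 111 320 m/degree with a cos(latitude)
correction in x, so the rise/run ratio against metre-valued elevations
is dimensionless; `geographic=False` treats cell sizes as already in
elevation units.

## Synthetic landscapes

The generator emulates only what the downstream statistics rely on:

- **Mixed native resolutions.** Three grid groups with cell sizes in
  ratio 1 : 4 : 8 (defaults 0.02°, 0.005°, 0.0025° over a 1° window),
  standing in for the coarse climate / medium vegetation / fine terrain
  products. The true products' ratio (1 km : 250 m : 30 m) would make
  the fine grid three orders of magnitude larger than the coarse one;
  1 : 4 : 8 preserves the "resample several scales down to the
  coarsest" structure at desk scale.
- **Spatial smoothness.** Each layer is Gaussian white noise smoothed
  by a separable Gaussian kernel (length-scale in map units, default
  0.1°) and rescaled min–max to its configured range, so configured
  bounds are attained exactly and a degenerate range (vmin = vmax)
  yields a constant layer — deliberately included in the default set
  (the bio14 analogue) so zero-importance pruning is exercised.
- **Known truth.** True suitability is `logistic(intercept + Σ coeffₖ ·
  zₖ)` over per-layer z-scores of the harmonized stack. Presences are
  sampled without replacement from valid cells with probability
  proportional to suitability and placed at cell centres (removing
  point-in-pixel ambiguity).

Per-layer random streams are derived from the master seed and a CRC32
of the layer name, so stacks are bit-identical across runs and layers
are insensitive to dictionary order. The generator makes no attempt to
match the covariance structure, cross-correlations or anisotropy of
real climate and satellite products — passing tests demonstrate the
*pipeline's* correctness and recovery behaviour, not performance on
real data.

## Pseudo-absences

Two policies interpret "environmentally dissimilar pixels":

- **Cluster exclusion (default).** Layers are z-scored (zero-variance
  layers contribute 0) and cells k-means-clustered in predictor space
  (k = 10 by default; the choice is a coarseness knob, not estimated).
  Cells of clusters containing no presence are eligible. This mirrors
  the workflow the package reproduces, but it degrades as presences
  become numerous: with hundreds of presences spread over a smooth
  landscape every cluster tends to be occupied and eligibility
  collapses (the stage then raises rather than silently relaxing).
- **Distance threshold.** Cells whose standardized Euclidean distance
  to the *nearest* presence exceeds a quantile (default 0.75) of that
  distance over all cells are eligible. This is always well-posed and
  concentrates the presence/absence contrast on the dimensions along
  which suitability actually declines; the parameter-recovery study
  uses it for exactly that reason.

Pseudo-absences are drawn uniformly without replacement from eligible
cells, never reuse a presence cell, and are placed at cell centres. No
geographic distance buffer is applied.

## Model stage

- **Tuning.** One forest per (ntree, mtry) grid cell, OOB error =
  1 − OOB accuracy on the feature table as extracted; best pair =
  argmin with ties broken toward smaller ntree, then smaller mtry (the
  cheaper model).
- **Balanced fold sampling.** Negatives without replacement, positives
  with replacement up to the per-class target (default: the negative
  count; positives already at or above the target are drawn without
  forced repetition). The target choice matches the rarer class to the
  commoner one rather than introducing a second free parameter.
- **Cross-validation.** Stratified k-fold (stratification keeps each
  fold from losing all of a 56-member positive class at k = 5),
  repeated with reshuffled folds; training accuracy is scored on the
  balanced training sample, validation accuracy on the untouched
  held-out fold. Reports exactly k × repeats records.
- **Importance.** Gini impurity-decrease importances (scikit-learn's
  normalized definition) averaged over one forest per seed in the fixed
  ten-seed list. Pruning uses the exact-zero test: a predictor never
  chosen for any split accumulates exactly 0.0 in floating point, so no
  tolerance is needed (a `zero_tol` flag exists should an accumulation
  scheme ever require it). Pruned predictors are dropped from both the
  table and the prediction stack, so perturbing them cannot change
  predictions.
- **Prediction.** HSI is computed from per-tree class votes (not
  averaged leaf probabilities), matching the majority-vote definition;
  the binary map thresholds it at 0.5. Nodata cells propagate.

All stage seeds derive from one master seed by hashing the stage name
(CRC32, masked below 2³¹), so stages rerun in isolation reproduce the
full-run outputs byte-for-byte.

## Areas and accuracy

HSI bins are half-open [lo, hi) of width 0.1 by default, the last bin
closed at 1.0 so an HSI of exactly 1 is counted; a bin width that does
not divide the unit interval is rejected. Values within 1e-9 of a bin
edge count as on the edge (guarding against 0.3 floating just below
3 × 0.1). Cell areas on geographic grids are `dx·dy·(111.32 km/°)² ·
cos(latitude)` per row (`planar` treats cell sizes as kilometres). The
suitable range defaults to HSI 0.6–0.9 — everything below 0.6 reads as
poor habitat — and its bounds must align with bin edges; misaligned
bounds raise rather than prorate. Note the suitable-range area and the
majority-vote presence area answer different questions and are not
reconciled: both are reported.

The confusion matrix is oriented rows = reference, columns = predicted,
with producer's accuracy dividing the diagonal by the **row** total and
user's accuracy by the **column** total — flipped relative to the
common Congalton layout, kept because it matches the equations this
package implements; an orientation flag swaps conventions. Kappa uses
the marginal-product formula directly; the single-class degenerate case
(N² equals the chance term) raises rather than returning a number. A
per-class accuracy with a zero marginal is reported as missing (None),
not 0. The agreement buckets are strong (K > 0.80), moderate
(0.40 ≤ K ≤ 0.80 — the 0.80 boundary is moderate), poor (K < 0.40).

## Parameter-recovery study

Each replicate: a 100×100-cell landscape of 12 layers — 3 causal
(standardized effect 1.0 each, length-scale 0.05°), 4 smooth noise
decoys, 5 constant decoys — truth intercept −1, 200 presences, 440
pseudo-absences by the distance policy, importance and final fit at
ntree = 200, mtry = 9 with the fixed ten-seed list. Scores: causal
layers occupying the top 3 mean-importance ranks, the 5 constants (and
only they) pruned at exactly 0, and Spearman correlation between the
predicted HSI and the true suitability over all cells. Replication
count is 10; the problem sizes were chosen so the full study completes
in about a minute on one CPU while leaving each forest several hundred
informative training rows.

Two known behaviours of this design are worth stating. First,
pseudo-absence selection operates in the full predictor space, so noise
layers acquire genuine (not artifactual) discriminative power; the
distance policy keeps that leakage small, but importance ranks are a
property of the presence/pseudo-absence *sample*, not of the truth
alone. Second, the Spearman target (> 0.6) is deliberately modest: a
forest trained on ~640 points cannot reproduce a smooth logistic
surface exactly, only its ordering.

## Known limitations

- No reprojection between coordinate systems; no CRS metadata beyond a
  tag on point sets.
- No spatial-autocorrelation-aware cross-validation; folds are
  stratified by class only, so validation accuracies are optimistic to
  the extent that presences are spatially clustered.
- No variance or confidence interval for kappa; no area-weighted
  accuracy estimators; no fragmentation/connectivity metrics.
- Model persistence relies on the ecosystem's standard serialization
  and is not portable across library versions.
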