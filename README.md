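# habitatrf

Random-forest habitat suitability mapping for presence-only species
records, exercised end-to-end on synthetic landscapes with known ground
truth.

The package re-implements, as a reusable and tested pipeline, the
species-distribution-modelling (SDM) workflow used to map habitat
suitability for an invasive bee from field/GBIF presence records and a
26-layer environmental stack (19 bioclimatic variables at a coarse
climate resolution, 3 satellite vegetation fractions at a medium
resolution, and elevation with slope/aspect/hillshade derived from a
fine DEM). It is aimed at ecologists who want the whole chain —
raster harmonization, pseudo-absence design, model tuning, suitability
mapping, area accounting, thematic accuracy — scriptable, seeded and
verifiable against landscapes where the truth is known.

## The method

1. **Harmonization.** Mixed-resolution layers are aligned to the
   coarsest (climate) grid by bilinear interpolation — each target cell
   takes the weighted average of the four nearest source cell centres
   (block-mean aggregation is available as an alternative). Terrain
   derivatives use Horn's 8-neighbour stencil.
2. **Pseudo-absences.** With presence-only data, "absences" are drawn
   in environmentally *dissimilar* pixels: the stack is z-scored per
   layer and either k-means-clustered (cells of presence-free clusters
   are eligible) or thresholded on the standardized distance to the
   nearest presence; 440 points are then drawn uniformly from eligible
   cells.
3. **Random forest.** ntree × mtry are grid-searched over
   {50, 100, 200, 500, 1000, 1500} × {3, 5, 7, 9, 10, 15, 20} by
   out-of-bag (OOB) error; stratified 5-fold cross-validation is
   repeated 10 times with imbalance-aware fold sampling (negatives
   without replacement, the rarer positives resampled with replacement
   up to the negative count). Gini impurity-decrease importance is
   averaged over ten fixed seeds [11, 17, 22, 34, 54, 68, 96, 108,
   224, 312]; predictors with mean importance exactly 0 are pruned.
4. **Mapping and accounting.** The Habitat Suitability Index (HSI) of a
   cell is the fraction of trees voting presence; the binary map is the
   majority vote (HSI ≥ 0.5). HSI is binned into 0.1-wide classes with
   per-class area in km² (cos-latitude corrected) and a configurable
   suitable range (default 0.6–0.9). Thematic accuracy reports overall,
   producer's and user's accuracy and Cohen's kappa

   K = (N·Σᵢxᵢᵢ − Σᵢ xᵢ₊·x₊ᵢ) / (N² − Σᵢ xᵢ₊·x₊ᵢ),

   categorized strong (K > 0.80), moderate (0.40–0.80) or poor (< 0.40).

Because real occurrence data and rasters are not bundled, a first-class
synthetic-landscape module generates smooth environmental fields at the
three native resolutions with configured ranges, a known logistic
true-suitability surface, and presences sampled proportional to it —
so every stage can be tested for parameter recovery.

## Worked example

The numbered scripts under `analysis/` run one complete study on a
26-layer synthetic landscape (100×100-cell harmonized grid, 56
presences, 440 pseudo-absences) and write tables under `results/study/`:

```bash
cd analysis
python 01_simulate_landscape.py
python 02_pseudo_absences.py
python 03_tune_and_validate.py
python 04_importance_and_map.py
python 05_areas_and_accuracy.py
python 06_parameter_recovery.py
```

Output of `03_tune_and_validate.py`:

```
OOB grid (6x7 fits): best ntree=500, mtry=5, error=0.0202
repeated CV: 50 fold records; mean training accuracy 100.00%, mean validation accuracy 97.94%
```

The tuned forest misclassifies ~2% of its out-of-bag samples; training
accuracy on the balanced fold samples is saturated while held-out
accuracy stays just below it, the expected overfitting direction.
`04_importance_and_map.py` ranks the three layers that actually drive
the synthetic truth (temperature, precipitation and non-tree-vegetation
analogues appear in the top three) and prunes the constant `bio14`
analogue at importance exactly 0:

```
top five predictors by mean importance:
  bio01                          0.2494
  percent_nontree_vegetation     0.0778
  bio12                          0.0613
  ...
pruned (mean importance exactly 0): ['bio14']
```

`05_areas_and_accuracy.py` then prints the area bookkeeping
(class areas summing to the 11 090 km² territory of the 1°×1° window,
a 2 795.7 km² suitable belt at HSI 0.6–0.9, presence 36.2% vs absence
63.8% of cells by majority vote) and the agreement of the binary map
with the thresholded truth. `06_parameter_recovery.py` repeats the
whole pipeline on ten landscapes with known drivers; all ten recover
the three causal layers in the top three importance ranks (HSI-truth
Spearman 0.69–0.84).

The same workflow is exposed as a CLI (`habitatrf run-all --config
cfg.yaml`, with per-stage subcommands `synth`, `harmonize`, `sample-pa`,
`tune`, `cv`, `importance`, `fit`, `areas`, `accuracy`) and as a plain
library (`habitatrf.Pipeline`).

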