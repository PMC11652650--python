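#!/usr/bin/env python
"""Generate pseudo-absence points in environmentally dissimilar cells.

With presence-only survey data the model needs manufactured absences.
This stage standardizes the harmonized predictor stack, scores each
cell's environmental distance to the nearest presence, marks the most
dissimilar quarter of the landscape as eligible, and draws 440 points
uniformly from it (never reusing a presence cell). The combined
presence / pseudo-absence table and the per-point predictor values
(the feature table) go to results/study/.
"""

import sys

import pandas as pd

from _common import STUDY_DIR, build_pipeline

def main() -> None:
    pipe = build_pipeline()
    occurrences = pipe.pseudo_absences()
    table = pipe.features()
    counts = pd.Series(occurrences.labels).value_counts()
    print(f"occurrences: {counts.to_dict()}")
    print(f"feature table: {len(table)} rows x {len(table.layer_names)} predictors "
          f"({table.n_dropped} dropped on nodata)")
    print(f"written to {STUDY_DIR / 'occurrences.csv'} and {STUDY_DIR / 'features.csv'}")

if __name__ == "__main__":
    sys.exit(main())
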